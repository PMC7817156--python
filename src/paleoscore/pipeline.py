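"""End-to-end orchestration of the analysis stages on synthetic data.

``run_pipeline`` chains: simulate -> sample QC -> PCA covariates -> scores ->
score-vs-time GLM with genomic empirical null -> ancestry-stratified tests ->
leave-top-k attenuation -> per-SNP date/ancestry LRTs -> PBS scan -> Qx ->
variance explained, writing every stage's tables (TSV) and results (JSON)
under one output directory together with a manifest sufficient to re-run the
pipeline identically.  All randomness flows from one seed through
deterministically spawned per-stage seeds, and all numeric output is formatted
so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype, pbs, popstruct, qx, scores, simulate, time_series, variance

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config object; every stage also runs standalone through the API."""

    preset: str = "neutral"
    seed: int = 0
    out_dir: str = "pipeline_out"
    # generator scale (kept desk-sized; see docs/methods.md)
    n_individuals: int = 200
    n_snps_null: int = 4000
    n_snps_trait: int = 60
    # analysis knobs
    b_null: int = 200
    b_qx: int = 500
    window_size: int = 20
    k_list: tuple = (1, 2, 5, 10)
    n_pcs: int = 10
    min_group_size: int = 20
    dedup_z: float = 7.0
    # desk-scale pools can lack a +-1% frequency match for tail-frequency
    # SNPs; fall back to the nearest candidates instead of aborting
    match_fallback: int = 20


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)


def _write_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage; halts with the failing stage named on any error."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    seeds = np.random.SeedSequence(config.seed).spawn(12)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["simulate", "null", "strata", "leave_top_k", "qx", "pca"], seeds
        )
    }
    manifest.stage_seeds = stage_seed
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("pca", _stage_pca),
        ("score", _stage_score),
        ("timeseries", _stage_timeseries),
        ("strata", _stage_strata),
        ("leave_top_k", _stage_leave_top_k),
        ("snp_regress", _stage_snp_regress),
        ("pbs", _stage_pbs),
        ("qx", _stage_qx),
        ("ve", _stage_ve),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(config, state, out, stage_seed, manifest)
        except Exception as exc:
            manifest.stage_status[name] = f"failed: {exc}"
            manifest.to_json(out / "manifest.json")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.stage_status[name] = "ok"
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", name, manifest.stage_seconds[name])

    for key, path in manifest.outputs.items():
        manifest.digests[key] = _sha256(path)
    manifest.to_json(out / "manifest.json")
    return manifest


def _register(manifest, out, **paths):
    for key, path in paths.items():
        manifest.outputs[key] = str(path)


def _stage_simulate(config, state, out, seed, manifest):
    cfg = simulate.make_preset(
        config.preset,
        n_individuals=config.n_individuals, n_snps_null=config.n_snps_null,
        n_snps_trait=config.n_snps_trait, seed=seed["simulate"],
    )
    data = simulate.simulate_dataset(cfg)
    state["data"] = data
    genotype.write_eigenstrat(
        data.matrix, out / "sim.geno", out / "sim.snp", out / "sim.ind"
    )
    genotype.write_sample_meta(data.meta, out / "sim_meta.tsv")
    _write_tsv(data.effect_table, out / "sim_effects.tsv")
    _write_tsv(data.q, out / "sim_q.tsv")
    _write_json(
        {"selected_snp_ids": data.selected_snp_ids, "preset": config.preset},
        out / "sim_truth.json",
    )
    _register(
        manifest, out,
        geno=out / "sim.geno", snp=out / "sim.snp", ind=out / "sim.ind",
        meta=out / "sim_meta.tsv", effects=out / "sim_effects.tsv",
        q=out / "sim_q.tsv", truth=out / "sim_truth.json",
    )


def _stage_qc(config, state, out, seed, manifest):
    data = state["data"]
    keep = set(genotype.filter_coverage(data.meta))
    keep &= set(genotype.filter_geography(data.meta))
    matrix = data.matrix.subset_samples([s for s in data.matrix.samples if s in keep])
    matrix, pairs = genotype.dedup_samples(matrix, z_threshold=config.dedup_z)
    state["matrix"] = matrix
    state["meta"] = data.meta[data.meta["sample_id"].isin(matrix.samples)]
    qc = {
        "n_input": data.matrix.n_samples, "n_after_qc": matrix.n_samples,
        "duplicate_pairs": [
            {"a": p.sample_a, "b": p.sample_b, "retained": p.retained} for p in pairs
        ],
    }
    _write_json(qc, out / "qc.json")
    _register(manifest, out, qc=out / "qc.json")


def _stage_pca(config, state, out, seed, manifest):
    model = popstruct.fit_reference_pca(state["matrix"], k=config.n_pcs)
    pcs = popstruct.project_samples(model, state["matrix"])
    state["pcs"] = pcs
    _write_tsv(pcs, out / "pcs.tsv")
    _register(manifest, out, pcs=out / "pcs.tsv")


def _stage_score(config, state, out, seed, manifest):
    data = state["data"]
    records = scores.score_matrix(state["matrix"], data.effect_table, weighted=True)
    state["scores"] = records
    _write_tsv(records, out / "scores.tsv")
    _register(manifest, out, scores=out / "scores.tsv")


def _stage_timeseries(config, state, out, seed, manifest):
    data = state["data"]
    fit = time_series.fit_score_glm(state["scores"], state["meta"], state["pcs"])
    test = time_series.empirical_null_pvalue(
        state["matrix"], data.effect_table, state["meta"], state["pcs"], data.pool,
        b=config.b_null, seed=seed["null"], match_fallback=config.match_fallback,
    )
    state["fit"], state["test"] = fit, test
    _write_json(
        {"fit": fit.as_dict(), "empirical": test.as_dict(), "b": config.b_null,
         "seed": seed["null"]},
        out / "timeseries.json",
    )
    _register(manifest, out, timeseries=out / "timeseries.json")


def _stage_strata(config, state, out, seed, manifest):
    data = state["data"]
    groups = time_series.assign_ancestry_group(
        data.q[data.q["sample_id"].isin(state["meta"]["sample_id"])], state["meta"]
    )
    res = time_series.stratified_score_test(
        state["matrix"], data.effect_table, state["meta"], state["pcs"], groups,
        data.pool, b=config.b_null, seed=seed["strata"],
        min_group_size=config.min_group_size, match_fallback=config.match_fallback,
    )
    payload = {
        "per_group": {g: t.as_dict() for g, t in res["per_group"].items()},
        "pairwise": res["pairwise"].to_dict(orient="records"),
        "skipped": res["skipped"],
        "seed": seed["strata"],
    }
    _write_json(payload, out / "strata.json")
    _register(manifest, out, strata=out / "strata.json")


def _stage_leave_top_k(config, state, out, seed, manifest):
    data = state["data"]
    table = time_series.leave_top_k(
        state["matrix"], data.effect_table, config.k_list, state["meta"],
        state["pcs"], seed=seed["leave_top_k"],
    )
    state["leave_top_k"] = table
    _write_tsv(table, out / "leave_top_k.tsv")
    _register(manifest, out, leave_top_k=out / "leave_top_k.tsv")


def _stage_snp_regress(config, state, out, seed, manifest):
    data = state["data"]
    scan = time_series.per_snp_scan(
        state["matrix"], data.trait_snp_ids, state["meta"], state["pcs"]
    )
    state["per_snp"] = scan
    _write_tsv(scan, out / "per_snp.tsv")
    ok = scan[scan["skip"] == ""]
    if len(ok) >= 3:
        reg = time_series.effect_vs_change_regression(data.effect_table, scan)
        _write_json(reg, out / "effect_vs_change.json")
        _register(manifest, out, effect_vs_change=out / "effect_vs_change.json")
    _register(manifest, out, per_snp=out / "per_snp.tsv")


def _stage_pbs(config, state, out, seed, manifest):
    data = state["data"]
    freq = simulate.build_pbs_freq_table(data)
    tables = []
    for focal in ("hunter_gatherer", "early_farmer", "steppe"):
        win = pbs.pbs_windows(
            freq, focal, "outgroup1", "outgroup2", window_size=config.window_size
        )
        win = pbs.percentile_flags(
            win, f"pbs_{focal}", trait_snp_ids=data.trait_snp_ids,
            window_size=config.window_size,
        )
        win.insert(0, "focal", focal)
        tables.append(win)
    _write_tsv(pd.concat(tables, ignore_index=True), out / "pbs_windows.tsv")
    _register(manifest, out, pbs=out / "pbs_windows.tsv")


def _stage_qx(config, state, out, seed, manifest):
    data = state["data"]
    pool_ids = data.pool["snp_id"]
    cov = qx.neutral_covariance(data.population_freqs.loc[pool_ids], min_snps=1000)
    res = qx.qx_empirical_p(
        data.effect_table, data.population_freqs, data.population_freqs.loc[pool_ids],
        cov, b=config.b_qx, seed=seed["qx"], match_fallback=config.match_fallback,
    )
    _write_json({**res.as_dict(), "seed": seed["qx"]}, out / "qx.json")
    _register(manifest, out, qx=out / "qx.json")


def _stage_ve(config, state, out, seed, manifest):
    data = state["data"]
    table = data.effect_table.merge(
        data.population_freqs[["hunter_gatherer", "outgroup1"]].rename(
            columns={"hunter_gatherer": "f_focal", "outgroup1": "f_out"}
        ),
        left_on="snp_id", right_index=True,
    )
    ve = variance.ve_table(table, f_within="freq", f_pop1="f_focal", f_pop2="f_out")
    _write_tsv(ve, out / "variance_explained.tsv")
    _register(manifest, out, ve=out / "variance_explained.tsv")
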