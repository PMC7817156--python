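"""Synthetic ancient-DNA datasets with known ground truth.

The generator emulates the study design the analysis modules expect: three
diverged source populations (hunter-gatherer-, Early-Farmer- and Steppe-like)
that split from a common ancestor, drift under a Wright-Fisher model with
optional directional selection at trait SNPs, and mix over time following an
admixture schedule; dated pseudohaploid individuals are sampled along the
transect with coverage-driven missingness, and two deeply diverged outgroup
populations stand in for present-day African and East Asian reference panels.

Selection acts on the *light* (non-effect) allele: the per-generation update
for the favored allele is q' = q(1+s)/(1+sq), followed by binomial drift with
2Ne draws.  Effect sizes are drawn from a heavy-tailed mixture (a few large,
many small), so presets can concentrate selection on the largest effects.

Null SNPs are independent (no LD); the generator does not emulate aDNA damage
or sequence-level processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix, SNPRecord

GENERATION_TIME = 29.0  # years per generation, common aDNA convention


@dataclass
class SimConfig:
    """All knobs of the generator; presets fill these coherently."""

    seed: int = 0
    n_snps_null: int = 20_000
    n_snps_trait: int = 100
    n_sources: int = 3
    ne: int = 10_000
    divergence_gens: tuple = (250, 250, 250)
    outgroup_divergence_gens: tuple = (2200, 1600)
    n_individuals: int = 300
    date_range: tuple = (15_000.0, 0.0)   # years BP, oldest first
    gen_time: float = GENERATION_TIME
    coverage_lognorm: tuple = (0.0, 1.0)  # mean, sd of log fold-coverage
    prop_large: float = 0.05
    large_beta: tuple = (0.5, 0.15)       # mean, sd of the large-effect component
    small_beta_scale: float = 0.04        # exponential scale of the small component
    gwas_n: float = 356_530.0
    selection_s: float = 0.0
    selected_top_k: int = 0
    selected_sources: tuple = (0, 1, 2)
    selection_start_bp: float | None = None
    select_during_divergence: bool = False
    selected_p0: float | None = None  # pin ancestral freq of selected SNPs
    # sweep footprint: linked flanking SNPs are dragged by a completed sweep;
    # emulated as a distance-decayed effective selection coefficient
    hitchhiking: bool = False
    footprint_decay_kb: float = 100.0
    footprint_max_kb: float = 250.0
    p0_range: tuple = (0.05, 0.95)
    snapshot_interval_gens: int = 5
    admix_concentration: float = 50.0
    preset: str = "custom"

    def __post_init__(self):
        if self.selection_s <= -1:
            raise ValueError("selection coefficient must exceed -1")
        if self.date_range[0] <= self.date_range[1]:
            raise ValueError("date_range must run oldest to youngest (years BP)")

    @property
    def n_snps(self) -> int:
        return self.n_snps_null + self.n_snps_trait

    @property
    def n_sampling_gens(self) -> int:
        span = self.date_range[0] - self.date_range[1]
        return int(np.ceil(span / self.gen_time))


PRESETS = ("neutral", "sweep-top", "branch-selection", "post-admixture")


def make_preset(name: str, **overrides) -> SimConfig:
    """Named study scenarios.

    ``neutral``: pure drift everywhere (the master calibration condition).
    ``sweep-top``: directional selection on the light allele of the five
    largest-effect SNPs in every source, concentrating the signal in the tail
    of the effect-size distribution.
    ``branch-selection``: strong selection at the single largest-effect SNP in
    one source only (source 0), the PBS branch-localization scenario.
    ``post-admixture``: selection at the top five SNPs starting only after
    5,000 BP, once the three ancestries are mixing.
    """
    if name == "neutral":
        cfg = SimConfig(preset=name)
    elif name == "sweep-top":
        cfg = SimConfig(preset=name, selection_s=0.02, selected_top_k=5)
    elif name == "branch-selection":
        cfg = SimConfig(
            preset=name, selection_s=0.05, selected_top_k=1,
            selected_sources=(0,), select_during_divergence=True,
            selected_p0=0.55,  # a completed sweep then shifts the branch ~0.5
            hitchhiking=True,  # the sweep drags its linked flank, as real sweeps do
        )
    elif name == "post-admixture":
        cfg = SimConfig(
            preset=name, selection_s=0.03, selected_top_k=5, selection_start_bp=5000.0
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return replace(cfg, **overrides)


@dataclass
class SimTruth:
    """Ground truth recorded by the frequency simulation."""

    p0: np.ndarray                      # ancestral frequencies, all SNPs
    source_start: np.ndarray            # (n_sources, L) post-divergence
    snapshot_gens: np.ndarray           # sampling-period generations recorded
    snapshots: np.ndarray               # (n_snapshots, n_sources, L) float32
    trait_traj: np.ndarray              # (n_gens+1, n_sources, n_trait)
    outgroup_freqs: np.ndarray          # (2, L)
    trait_idx: np.ndarray
    selection: np.ndarray               # (n_sources, n_trait) applied s
    config: SimConfig

    @property
    def source_final(self) -> np.ndarray:
        """Source frequencies at the end of the sampling period (P matrix)."""
        return np.asarray(self.snapshots[-1], dtype=float)


def _drift(p, gens, ne, rng, s=None, sel_mask=None):
    """Binomial Wright-Fisher drift; optional selection on the light allele.

    ``p`` tracks the dark/alternate allele; with light-allele advantage s the
    deterministic update is p' = p / (1 + s (1 - p)).
    """
    p = np.array(p, dtype=float)
    for _ in range(int(gens)):
        if s is not None and np.any(s != 0):
            psel = p if sel_mask is None else p[sel_mask]
            upd = psel / (1.0 + s * (1.0 - psel))
            if sel_mask is None:
                p = upd
            else:
                p[sel_mask] = upd
        p = rng.binomial(2 * ne, p) / (2.0 * ne)
    return p


def simulate_source_frequencies(config: SimConfig, betas=None, rng=None) -> SimTruth:
    """Simulate ancestral, source, and outgroup allele-frequency trajectories.

    ``betas`` (trait effect sizes) determine which SNPs carry selection when
    the preset targets the largest effects; pass the vector produced by
    :func:`simulate_effect_sizes` (or None for neutral runs).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.n_snps
    p0 = rng.uniform(*config.p0_range, size=L)
    trait_idx = np.sort(rng.choice(L, size=config.n_snps_trait, replace=False))

    # selection design: s per (source, SNP); trait SNPs carry the configured
    # coefficients, and with hitchhiking enabled a completed sweep drags its
    # linked flank through a distance-decayed effective coefficient
    sel = np.zeros((config.n_sources, config.n_snps_trait))
    sel_full = np.zeros((config.n_sources, L))
    if config.selection_s != 0 and config.selected_top_k > 0:
        if betas is None:
            raise ValueError("selected_top_k > 0 requires effect sizes")
        top = np.argsort(-np.abs(np.asarray(betas)))[: config.selected_top_k]
        for k in config.selected_sources:
            sel[k, top] = config.selection_s
        sel_full[:, trait_idx] = sel
        if config.selected_p0 is not None:
            p0[trait_idx[top]] = config.selected_p0
        if config.hitchhiking:
            recs = make_snp_records(config)
            chrom = np.array([r.chrom for r in recs])
            pos = np.array([r.pos for r in recs], dtype=float)
            for j in trait_idx[top]:
                near = (chrom == chrom[j]) & (
                    np.abs(pos - pos[j]) <= config.footprint_max_kb * 1000
                )
                decay = config.selection_s * np.exp(
                    -np.abs(pos[near] - pos[j]) / (config.footprint_decay_kb * 1000)
                )
                for k in config.selected_sources:
                    sel_full[k, near] = np.maximum(sel_full[k, near], decay)

    # divergence drift per source (selection optionally active on the branch)
    source_start = np.empty((config.n_sources, L))
    for k in range(config.n_sources):
        mask = None
        if config.select_during_divergence and sel_full[k].any():
            mask = sel_full[k] != 0
            s_vec = sel_full[k][mask]
        p = np.array(p0)
        for _ in range(int(config.divergence_gens[k])):
            if mask is not None:
                p[mask] = p[mask] / (1.0 + s_vec * (1.0 - p[mask]))
            p = rng.binomial(2 * config.ne, p) / (2.0 * config.ne)
        source_start[k] = p

    outgroup = np.empty((2, L))
    for k, gens in enumerate(config.outgroup_divergence_gens):
        outgroup[k] = _drift(p0, gens, config.ne, rng)

    # sampling period: generation 0 = oldest date
    n_gens = config.n_sampling_gens
    sel_start_gen = 0
    if config.selection_start_bp is not None:
        sel_start_gen = int(
            np.floor((config.date_range[0] - config.selection_start_bp) / config.gen_time)
        )
    p = source_start.copy()
    snap_gens, snaps = [0], [p.astype(np.float32).copy()]
    traj = np.empty((n_gens + 1, config.n_sources, config.n_snps_trait), dtype=np.float32)
    traj[0] = p[:, trait_idx]
    active = sel_full != 0
    for g in range(1, n_gens + 1):
        if g > sel_start_gen and active.any():
            p = np.where(active, p / (1.0 + sel_full * (1.0 - p)), p)
        p = rng.binomial(2 * config.ne, p) / (2.0 * config.ne)
        traj[g] = p[:, trait_idx]
        if g % config.snapshot_interval_gens == 0 or g == n_gens:
            snap_gens.append(g)
            snaps.append(p.astype(np.float32).copy())
    return SimTruth(
        p0=p0, source_start=source_start, snapshot_gens=np.array(snap_gens),
        snapshots=np.stack(snaps), trait_traj=traj, outgroup_freqs=outgroup,
        trait_idx=trait_idx, selection=sel, config=config,
    )


def default_admixture_schedule(date_bp):
    """Target ancestry fractions (HG, EF, Steppe) as a function of date BP.

    Hunter-gatherer only before 8,500 BP; Early Farmer ancestry ramps in over
    8,500-5,000 BP; Steppe ancestry arrives after 5,000 BP and plateaus at 45%
    by 3,500 BP.  Purely a plausible default, not an inference.
    """
    date_bp = np.asarray(date_bp, dtype=float)
    ef = np.where(
        date_bp >= 8500, 0.0,
        np.where(date_bp >= 5000, 0.75 * (8500 - date_bp) / 3500, 0.75),
    )
    steppe = np.where(
        date_bp >= 5000, 0.0, 0.45 * np.minimum((5000 - date_bp) / 1500, 1.0)
    )
    ef = ef * (1.0 - steppe)
    hg = 1.0 - ef - steppe
    return np.stack([hg, ef, steppe], axis=-1)


def simulate_individuals(config: SimConfig, truth: SimTruth, rng=None):
    """Dated pseudohaploid individuals sampled along the transect.

    Each individual draws a date (uniform over the range), ancestry fractions
    (Dirichlet noise around the schedule), a fold-coverage (lognormal), one
    Bernoulli pseudohaploid call per SNP from its ancestry-weighted expected
    frequency, and then loses each call independently with probability
    exp(-coverage).

    Returns ``(GenotypeMatrix, meta DataFrame, Q DataFrame)``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_individuals
    dates = np.sort(rng.uniform(config.date_range[1], config.date_range[0], size=n))[::-1]
    target = default_admixture_schedule(dates)
    alpha = config.admix_concentration * target + 0.01
    q = np.vstack([rng.dirichlet(a) for a in alpha])
    if config.n_sources != 3:
        raise ValueError("the default admixture schedule defines 3 sources")

    gens = np.clip(
        np.round((config.date_range[0] - dates) / config.gen_time).astype(int),
        0, config.n_sampling_gens,
    )
    snap_of = np.searchsorted(truth.snapshot_gens, gens, side="left")
    snap_of = np.clip(snap_of, 0, len(truth.snapshot_gens) - 1)

    L = config.n_snps
    p_exp = np.empty((n, L))
    for si in np.unique(snap_of):
        rows = snap_of == si
        p_exp[rows] = q[rows] @ np.asarray(truth.snapshots[si], dtype=float)
    # trait SNPs at exact generation resolution
    p_exp[:, truth.trait_idx] = np.einsum(
        "nk,nkm->nm", q, truth.trait_traj[gens].astype(float)
    )

    calls = (rng.random((n, L)) < p_exp).astype(np.int8)
    coverage = rng.lognormal(*config.coverage_lognorm, size=n)
    miss = rng.random((n, L)) < np.exp(-coverage)[:, None]
    calls[miss] = MISSING

    lon = 5.0 + 40.0 * q[:, 2] + rng.uniform(-12, 12, size=n)
    lat = 40.0 + 12.0 * q[:, 0] + rng.uniform(-4, 4, size=n)
    ids = [f"anc{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": ids, "date_bp": dates,
            "lat": np.clip(lat, 35.5, 70.0), "lon": np.clip(lon, -10.0, 59.5),
            "coverage": coverage,
        }
    )
    qdf = pd.DataFrame(q, columns=["hunter_gatherer", "early_farmer", "steppe"])
    qdf.insert(0, "sample_id", ids)
    matrix = GenotypeMatrix(
        samples=ids, snps=make_snp_records(config), calls=calls, ploidy=1
    )
    return matrix, meta, qdf


_BASES = np.array(list("ACGT"))


def make_snp_records(config: SimConfig) -> list[SNPRecord]:
    """Deterministic SNP records: 22 chromosomes, 10 kb spacing."""
    rng = np.random.default_rng(config.seed + 2)
    L = config.n_snps
    per_chrom = int(np.ceil(L / 22))
    recs = []
    for j in range(L):
        ref, alt = _BASES[rng.choice(4, size=2, replace=False)]
        recs.append(
            SNPRecord(
                id=f"snp{j:06d}", chrom=str(j // per_chrom + 1),
                pos=(j % per_chrom) * 10_000 + 1, ref_allele=str(ref), alt_allele=str(alt),
            )
        )
    return recs


def simulate_effect_sizes(config: SimConfig, rng=None) -> np.ndarray:
    """Trait effect sizes: heavy-tailed mixture of few large and many small.

    Returns the |beta| vector (dark-oriented by construction).  Standard errors
    downstream are scaled to the nominal GWAS sample size.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    m = config.n_snps_trait
    large = rng.random(m) < config.prop_large
    n_large = max(int(large.sum()), 1) if m >= 20 else int(large.sum())
    if large.sum() == 0 and m >= 20:
        large[rng.integers(m)] = True  # guarantee a heavy tail
    beta = rng.exponential(config.small_beta_scale, size=m)
    mu, sd = config.large_beta
    beta[large] = np.abs(rng.normal(mu, sd, size=int(large.sum())))
    return beta


@dataclass
class SimData:
    """A complete synthetic study: genotypes, metadata, panels and truth."""

    matrix: GenotypeMatrix
    meta: pd.DataFrame
    q: pd.DataFrame
    effect_table: pd.DataFrame
    pool: pd.DataFrame                 # null SNPs: snp_id, freq
    population_freqs: pd.DataFrame     # sources + outgroups, indexed by snp_id
    truth: SimTruth
    config: SimConfig

    @property
    def trait_snp_ids(self) -> list[str]:
        return list(self.effect_table["snp_id"])

    @property
    def selected_snp_ids(self) -> list[str]:
        chosen = np.flatnonzero(self.truth.selection.any(axis=0))
        ids = np.array(self.matrix.snp_ids)[self.truth.trait_idx[chosen]]
        return [str(s) for s in ids]


POPULATIONS = ("hunter_gatherer", "early_farmer", "steppe", "outgroup1", "outgroup2")


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimData:
    """Run the whole generator: frequencies, individuals, panels, pools."""
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    betas = simulate_effect_sizes(config, rng)
    truth = simulate_source_frequencies(config, betas=betas, rng=rng)
    matrix, meta, q = simulate_individuals(config, truth, rng=rng)

    snp_ids = np.array(matrix.snp_ids)
    sample_freq = matrix.allele_frequencies()
    recs = {r.id: r for r in matrix.snps}
    trait_ids = snp_ids[truth.trait_idx]
    se = 1.0 / np.sqrt(
        2.0 * config.gwas_n * np.clip(sample_freq[truth.trait_idx], 0.02, 0.98)
        * (1.0 - np.clip(sample_freq[truth.trait_idx], 0.02, 0.98))
    )
    from scipy import stats as _st

    effect_table = pd.DataFrame(
        {
            "snp_id": trait_ids,
            "chrom": [recs[s].chrom for s in trait_ids],
            "pos": [recs[s].pos for s in trait_ids],
            "effect_allele": [recs[s].alt_allele for s in trait_ids],
            "other_allele": [recs[s].ref_allele for s in trait_ids],
            "beta": betas,
            "se": se,
            "pval": 2.0 * _st.norm.sf(betas / se),
            "freq": sample_freq[truth.trait_idx],
        }
    )
    null_idx = np.setdiff1d(np.arange(config.n_snps), truth.trait_idx)
    pool = pd.DataFrame({"snp_id": snp_ids[null_idx], "freq": sample_freq[null_idx]})
    pool = pool[np.isfinite(pool["freq"])].reset_index(drop=True)

    pop = np.vstack([truth.source_final, truth.outgroup_freqs])
    population_freqs = pd.DataFrame(pop.T, index=snp_ids, columns=list(POPULATIONS))
    return SimData(
        matrix=matrix, meta=meta, q=q, effect_table=effect_table, pool=pool,
        population_freqs=population_freqs, truth=truth, config=config,
    )


def effective_sample_sizes(q: pd.DataFrame, matrix: GenotypeMatrix) -> pd.DataFrame:
    """Effective per-source sample size per SNP for ADMIXTURE-style frequencies.

    n_{k,j} = sum over individuals with a non-missing call at SNP j of that
    individual's ancestry fraction for source k (haploid counts).
    """
    called = (matrix.calls != MISSING).astype(float)       # (n, L)
    frac = q[["hunter_gatherer", "early_farmer", "steppe"]].to_numpy(float)
    n_eff = frac.T @ called                                 # (3, L)
    return pd.DataFrame(
        n_eff.T, index=matrix.snp_ids,
        columns=["hunter_gatherer", "early_farmer", "steppe"],
    )


def build_pbs_freq_table(
    data: SimData, outgroup_n: float = 100.0
) -> pd.DataFrame:
    """Assemble the PBS frequency table from a simulated dataset.

    Source frequencies come from the truth P matrix with effective sample
    sizes from ancestry-weighted call counts; outgroup frequencies use a fixed
    panel size.  Includes per-SNP missing rates for the >90% exclusion.
    """
    m = data.matrix
    n_eff = effective_sample_sizes(data.q, m)
    out = pd.DataFrame(
        {
            "snp_id": m.snp_ids,
            "chrom": [r.chrom for r in m.snps],
            "pos": [r.pos for r in m.snps],
            "missing_rate": m.missing_rate_per_snp(),
        }
    )
    for k, popname in enumerate(("hunter_gatherer", "early_farmer", "steppe")):
        out[f"p_{popname}"] = data.truth.source_final[k]
        out[f"n_{popname}"] = np.maximum(n_eff[popname].to_numpy(), 1.0 + 1e-9)
    for k, popname in enumerate(("outgroup1", "outgroup2")):
        out[f"p_{popname}"] = data.truth.outgroup_freqs[k]
        out[f"n_{popname}"] = outgroup_n
    return out
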