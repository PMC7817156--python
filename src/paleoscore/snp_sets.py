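"""Trait-SNP panel construction: dark-allele orientation, LD/distance clumping,
frequency-matched null sets and cross-panel tagging classification.

The effect table is a plain :class:`pandas.DataFrame` with columns
``snp_id, chrom, pos, effect_allele, other_allele, beta, se, pval, freq``
(GWAS summary-statistics dialect).  After :func:`orient_to_dark` every row's
effect allele is the trait-increasing ("dark") allele and all betas are
non-negative, which is what the score formulas downstream assume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "freq",
)


def load_curated_panel() -> pd.DataFrame:
    """Synthetic stand-in for a hand-curated multi-ancestry pigmentation panel.

    The rsIDs are literature pigmentation loci, but positions and alleles are
    synthetic placeholders (see the file header); the panel exists so the
    unweighted-score path has a concrete 18-SNP input.
    """
    from importlib.resources import files

    path = files("paleoscore.data").joinpath("curated_snps_synthetic.tsv")
    return pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "chrom": str})


def read_effect_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in EFFECT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"effect table missing columns: {missing}")
    return table


def write_effect_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def orient_to_dark(table: pd.DataFrame) -> pd.DataFrame:
    """Flip rows so the effect allele is always the trait-increasing allele.

    Rows with negative beta have effect/other alleles swapped, beta negated and
    the effect-allele frequency complemented.  Zero-beta rows are kept as-is
    with a warning.  Idempotent.
    """
    if not np.isfinite(table["beta"]).all():
        raise ValueError("non-finite beta in effect table")
    out = table.copy()
    flip = out["beta"] < 0
    if (out["beta"] == 0).any():
        logger.warning("%d SNPs with beta == 0 left unoriented", int((out["beta"] == 0).sum()))
    ea = out.loc[flip, "effect_allele"].copy()
    out.loc[flip, "effect_allele"] = out.loc[flip, "other_allele"]
    out.loc[flip, "other_allele"] = ea
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "freq"] = 1.0 - out.loc[flip, "freq"]
    return out


def _r2_matrix(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of genotype dosages, missing-aware per pair."""
    from .genotype import MISSING

    x = np.ma.masked_equal(calls.astype(float), MISSING)
    r = np.ma.corrcoef(x, rowvar=False)
    return np.asarray(r.filled(0.0)) ** 2


def clump_greedy_r2(
    table: pd.DataFrame,
    reference,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.05,
    window_kb: float = 250.0,
) -> pd.DataFrame:
    """Greedy LD clumping of GWAS hits against a reference genotype panel.

    Significant SNPs are taken best-first by p-value; each index SNP removes
    every remaining SNP within ``window_kb`` on the same chromosome whose
    reference-panel r-squared with it reaches ``r2_threshold``.  SNPs absent
    from the reference cannot be pruned and are excluded with a warning.
    """
    ref_ids = {s: j for j, s in enumerate(reference.snp_ids)}
    sig = table[table["pval"] <= p_threshold].copy()
    absent = ~sig["snp_id"].isin(ref_ids)
    if absent.any():
        logger.warning(
            "%d clump candidates absent from the reference panel; excluded",
            int(absent.sum()),
        )
        sig = sig[~absent]
    sig = sig.sort_values(["pval", "snp_id"], kind="mergesort").reset_index(drop=True)

    window = window_kb * 1000.0
    removed = np.zeros(len(sig), dtype=bool)
    keep_rows = []
    pos = sig["pos"].to_numpy(float)
    chrom = sig["chrom"].to_numpy()
    cols = np.array([ref_ids[s] for s in sig["snp_id"]])
    calls = reference.calls
    for i in range(len(sig)):
        if removed[i]:
            continue
        keep_rows.append(i)
        near = (
            ~removed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        near[i] = False
        if near.any():
            idx = np.flatnonzero(near)
            sub = _r2_matrix(calls[:, np.concatenate(([cols[i]], cols[idx]))])
            removed[idx[sub[0, 1:] >= r2_threshold]] = True
    return sig.iloc[keep_rows].reset_index(drop=True)


def clump_by_distance(table: pd.DataFrame, min_kb: float = 100.0) -> pd.DataFrame:
    """Greedy physical-distance clumping: best p first, drop SNPs within ``min_kb``."""
    window = min_kb * 1000.0
    ordered = table.sort_values(["pval", "snp_id"], kind="mergesort").reset_index(drop=True)
    kept: dict[str, list[float]] = {}
    keep_rows = []
    for i, row in ordered.iterrows():
        near = kept.get(row["chrom"], [])
        if all(abs(row["pos"] - p) >= window for p in near):
            keep_rows.append(i)
            kept.setdefault(row["chrom"], []).append(row["pos"])
    return ordered.iloc[keep_rows].reset_index(drop=True)


def match_frequency(
    target_freqs,
    pool_freqs,
    n_sets: int,
    seed,
    tolerance: float = 0.01,
    exclude=None,
    fallback_nearest: int = 0,
) -> np.ndarray:
    """Draw ``n_sets`` frequency-matched null SNP sets from a genome-wide pool.

    For every target frequency, candidates are pool entries within
    ``tolerance`` (default +-1%).  Each replicate set draws one candidate per
    target uniformly, without replacement within the set (with replacement
    across sets).  Returns an ``(n_sets, n_targets)`` array of pool indices.

    Parameters
    ----------
    target_freqs : array of effect-allele frequencies of the trait panel.
    pool_freqs : array of effect-allele frequencies of the candidate pool.
    exclude : optional boolean mask or index array of pool entries barred from
        candidacy (e.g. the trait SNPs themselves when they live in the pool).
    fallback_nearest : with the default 0, an empty candidate bin is an error;
        a positive value instead takes that many nearest-frequency pool SNPs
        (logged) — useful for small desk-scale pools where a tail-frequency
        target may have no neighbor within the tolerance.
    """
    rng = np.random.default_rng(seed)
    target_freqs = np.asarray(target_freqs, dtype=float)
    pool_freqs = np.asarray(pool_freqs, dtype=float)
    barred = np.zeros(len(pool_freqs), dtype=bool)
    if exclude is not None:
        barred[np.asarray(exclude)] = True

    candidates = []
    for t in target_freqs:
        cand = np.flatnonzero((np.abs(pool_freqs - t) <= tolerance) & ~barred)
        if cand.size == 0:
            if fallback_nearest > 0:
                free = np.flatnonzero(~barred)
                cand = free[np.argsort(np.abs(pool_freqs[free] - t))[:fallback_nearest]]
                logger.warning(
                    "no pool SNP within +-%g of frequency %.4f; using the %d "
                    "nearest (worst gap %.4f)",
                    tolerance, t, cand.size, float(np.abs(pool_freqs[cand] - t).max()),
                )
            else:
                raise ValueError(
                    f"no frequency-matched candidates within +-{tolerance} "
                    f"of target frequency {t:.4f}"
                )
        candidates.append(cand)

    n_targets = len(target_freqs)
    out = np.empty((n_sets, n_targets), dtype=np.int64)
    for b in range(n_sets):
        used: set[int] = set()
        for t in range(n_targets):
            cand = candidates[t]
            pick = int(cand[rng.integers(cand.size)])
            if pick in used:
                free = cand[~np.isin(cand, list(used))]
                if free.size == 0:
                    raise ValueError(
                        f"candidate bin exhausted for target frequency "
                        f"{target_freqs[t]:.4f} (within-set sampling is without "
                        "replacement)"
                    )
                pick = int(free[rng.integers(free.size)])
            used.add(pick)
            out[b, t] = pick
    return out


def tagging_classification(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    reference,
    max_dist: float = 1_000_000.0,
) -> pd.DataFrame:
    """Classify panel-A SNPs by how well panel B tags them in the reference.

    Classes, in priority order: ``shared`` (same SNP id in both panels),
    ``r2_ge_0.8``, ``r2_ge_0.5`` (max r-squared with any panel-B SNP within
    1 Mb), else ``untagged``.  SNPs absent from the reference are ``untagged``
    with a warning.
    """
    ref_ids = {s: j for j, s in enumerate(reference.snp_ids)}
    b_ids = set(panel_b["snp_id"])
    b_in_ref = panel_b[panel_b["snp_id"].isin(ref_ids)]
    classes = []
    for _, row in panel_a.iterrows():
        if row["snp_id"] in b_ids:
            classes.append("shared")
            continue
        if row["snp_id"] not in ref_ids:
            logger.warning("SNP %s absent from reference; classed untagged", row["snp_id"])
            classes.append("untagged")
            continue
        near = b_in_ref[
            (b_in_ref["chrom"] == row["chrom"])
            & (np.abs(b_in_ref["pos"] - row["pos"]) <= max_dist)
        ]
        if near.empty:
            classes.append("untagged")
            continue
        cols = [ref_ids[row["snp_id"]]] + [ref_ids[s] for s in near["snp_id"]]
        r2 = _r2_matrix(reference.calls[:, cols])[0, 1:]
        best = float(np.nanmax(r2)) if r2.size else 0.0
        if best >= 0.8:
            classes.append("r2_ge_0.8")
        elif best >= 0.5:
            classes.append("r2_ge_0.5")
        else:
            classes.append("untagged")
    out = panel_a.copy()
    out["tag_class"] = classes
    return out
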