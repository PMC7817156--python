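"""The Qx test for polygenic selection.

Qx asks whether trait-associated allele frequencies are overdispersed across
populations relative to genome-wide (neutral) expectation.  Mean additive
genetic values Z_pop = 2 * sum_l beta_l * f_l,pop are mean-centered across
populations, scaled by the additive variance term sqrt(V_A) with
V_A = 4 * sum_l beta_l^2 * eps_l (1 - eps_l) (eps_l the across-population mean
frequency), and whitened against a neutral covariance matrix F estimated from
genome-wide SNPs on the (n_pop - 1)-dimensional subspace orthogonal to the
constant vector.  The sum of squared whitened components is Qx, compared either
to its chi-squared reference distribution with n_pop - 1 degrees of freedom or
to an empirical null built from frequency-matched random SNP sets (matching on
minor-allele frequency, +-2% by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .snp_sets import match_frequency

logger = logging.getLogger(__name__)


@dataclass
class QxResult:
    qx: float
    m_snps: int
    n_populations: int
    chi2_p: float
    empirical_p: float | None = None
    b_null: int | None = None

    def as_dict(self) -> dict:
        return {
            "qx": self.qx, "m_snps": self.m_snps,
            "n_populations": self.n_populations, "chi2_p": self.chi2_p,
            "empirical_p": self.empirical_p, "b_null": self.b_null,
        }


def genetic_values(effect_table: pd.DataFrame, population_freqs: pd.DataFrame) -> np.ndarray:
    """Mean additive genetic value per population: Z = 2 * sum(beta * freq).

    ``population_freqs`` is indexed by snp_id with one column per population;
    every trait SNP must have a frequency in every population.
    """
    missing = [s for s in effect_table["snp_id"] if s not in population_freqs.index]
    if missing:
        raise ValueError(f"missing population frequencies for SNPs: {missing[:5]}")
    f = population_freqs.loc[effect_table["snp_id"]].to_numpy(float)
    if np.isnan(f).any():
        i, j = np.argwhere(np.isnan(f))[0]
        raise ValueError(
            f"missing frequency for SNP {effect_table['snp_id'].iloc[i]} in "
            f"population {population_freqs.columns[j]}"
        )
    beta = effect_table["beta"].to_numpy(float)
    return 2.0 * beta @ f


def neutral_covariance(genomewide_freqs: pd.DataFrame, min_snps: int = 10_000) -> pd.DataFrame:
    """Across-population covariance of scaled, centered neutral frequencies.

    Each SNP contributes x = (f - fbar) / sqrt(fbar (1 - fbar)) with fbar the
    unweighted across-population mean; the covariance is the average outer
    product, which is positive semi-definite by construction.  SNPs fixed in
    the pooled sample are dropped.
    """
    pops = list(genomewide_freqs.columns)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations for a neutral covariance")
    f = genomewide_freqs.to_numpy(float)
    fbar = f.mean(axis=1)
    keep = (fbar > 0) & (fbar < 1)
    f, fbar = f[keep], fbar[keep]
    if len(f) < min_snps:
        logger.warning(
            "neutral covariance built from %d SNPs; >= %d recommended", len(f), min_snps
        )
    x = (f - fbar[:, None]) / np.sqrt(fbar * (1 - fbar))[:, None]
    cov = x.T @ x / len(x)
    return pd.DataFrame(cov, index=pops, columns=pops)


def _contrast_matrix(n: int) -> np.ndarray:
    """(n-1) x n orthonormal basis of the subspace orthogonal to the 1-vector."""
    full = np.linalg.svd(np.eye(n) - np.ones((n, n)) / n)[0]
    return full[:, : n - 1].T


def _qx_from_values(z: np.ndarray, beta: np.ndarray, eps: np.ndarray, whiten: np.ndarray):
    va = 4.0 * float(beta**2 @ (eps * (1 - eps)))
    if va <= 0:
        raise ValueError("zero additive variance: all trait SNPs fixed or beta = 0")
    zc = (z - z.mean(axis=-1, keepdims=True)) / np.sqrt(va)
    x = zc @ whiten.T
    return (x**2).sum(axis=-1)


def qx_statistic(
    effect_table: pd.DataFrame,
    trait_freqs: pd.DataFrame,
    covariance: pd.DataFrame,
) -> QxResult:
    """Qx for one trait panel against a precomputed neutral covariance.

    Qx is zero when all populations share identical trait-SNP frequencies and
    is referred to a chi-squared distribution with n_pop - 1 df.
    """
    pops = list(covariance.columns)
    z = genetic_values(effect_table, trait_freqs[pops])
    f = trait_freqs.loc[effect_table["snp_id"], pops].to_numpy(float)
    eps = f.mean(axis=1)
    beta = effect_table["beta"].to_numpy(float)

    t = _contrast_matrix(len(pops))
    reduced = t @ covariance.to_numpy(float) @ t.T
    try:
        chol = np.linalg.cholesky(reduced)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "neutral covariance singular on the contrast subspace; "
            "build it from more SNPs"
        ) from exc
    whiten = np.linalg.solve(chol, t)
    qx = float(_qx_from_values(z, beta, eps, whiten))
    df = len(pops) - 1
    return QxResult(
        qx=qx, m_snps=len(effect_table), n_populations=len(pops),
        chi2_p=float(stats.chi2.sf(qx, df)),
    )


def qx_empirical_p(
    effect_table: pd.DataFrame,
    trait_freqs: pd.DataFrame,
    pool_freqs: pd.DataFrame,
    covariance: pd.DataFrame,
    b: int = 10_000,
    tolerance: float = 0.02,
    seed=0,
    match_fallback: int = 0,
) -> QxResult:
    """Qx with an empirical p from minor-allele-frequency-matched null sets.

    Each of ``b`` replicates substitutes every trait SNP with a random pool SNP
    whose pooled minor-allele frequency is within ``tolerance`` (+-2% default),
    keeping the trait effect sizes, and recomputes Qx.  The trait SNPs must not
    be in the pool.  p = (1 + #{null >= observed}) / (b + 1).
    """
    pops = list(covariance.columns)
    observed = qx_statistic(effect_table, trait_freqs, covariance)

    pool = pool_freqs[pops].to_numpy(float)
    pool_maf = np.minimum(pool.mean(axis=1), 1 - pool.mean(axis=1))
    f_trait = trait_freqs.loc[effect_table["snp_id"], pops].to_numpy(float)
    target_maf = np.minimum(f_trait.mean(axis=1), 1 - f_trait.mean(axis=1))

    draws = match_frequency(
        target_maf, pool_maf, n_sets=b, seed=seed, tolerance=tolerance,
        fallback_nearest=match_fallback,
    )
    beta = effect_table["beta"].to_numpy(float)
    t = _contrast_matrix(len(pops))
    chol = np.linalg.cholesky(t @ covariance.to_numpy(float) @ t.T)
    whiten = np.linalg.solve(chol, t)

    f_null = pool[draws]                     # (b, M, n_pops)
    z_null = 2.0 * np.einsum("m,bmp->bp", beta, f_null)
    eps_null = f_null.mean(axis=2)           # (b, M)
    va = 4.0 * np.einsum("m,bm->b", beta**2, eps_null * (1 - eps_null))
    zc = (z_null - z_null.mean(axis=1, keepdims=True)) / np.sqrt(va)[:, None]
    null_qx = ((zc @ whiten.T) ** 2).sum(axis=1)

    p = (1 + int((null_qx >= observed.qx).sum())) / (b + 1)
    observed.empirical_p = float(p)
    observed.b_null = b
    return observed


def ordered_subset_scan(
    effect_table: pd.DataFrame,
    trait_freqs: pd.DataFrame,
    pool_freqs: pd.DataFrame,
    covariance: pd.DataFrame,
    k_list,
    b: int = 10_000,
    tolerance: float = 0.02,
    seed=0,
    drop_top=(),
    match_fallback: int = 0,
) -> pd.DataFrame:
    """Qx over nested top-k panels ranked by |beta| (and optional complements).

    For each k in ``k_list`` the test runs on the k largest-|beta| SNPs; for
    each j in ``drop_top`` it runs on the panel with the top-j SNPs removed.
    Returns one row per subset with Qx, chi-squared and empirical p-values.
    """
    ranked = effect_table.reindex(
        effect_table["beta"].abs().sort_values(ascending=False, kind="mergesort").index
    ).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_list:
        if not 1 <= k <= len(ranked):
            raise ValueError(f"k={k} outside 1..{len(ranked)}")
        res = qx_empirical_p(
            ranked.iloc[:k], trait_freqs, pool_freqs, covariance,
            b=b, tolerance=tolerance, seed=int(rng.integers(2**31)),
            match_fallback=match_fallback,
        )
        rows.append({"subset": f"top_{k}", **res.as_dict()})
    for j in drop_top:
        res = qx_empirical_p(
            ranked.iloc[j:], trait_freqs, pool_freqs, covariance,
            b=b, tolerance=tolerance, seed=int(rng.integers(2**31)),
            match_fallback=match_fallback,
        )
        rows.append({"subset": f"drop_top_{j}", **res.as_dict()})
    return pd.DataFrame(rows)
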