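"""Score-vs-time regression with a genome-wide empirical null, ancestry
stratification, leave-top-k attenuation, and per-SNP time/ancestry tests.

Model: the (weighted or unweighted) genetic score S_i of individual i with m_i
genotyped panel SNPs is a binomial proportion with

    logit(p_i) = alpha + b_date * date_i + b_lat * lat_i + b_lon * lon_i
                 + b_PC1 * PC1_i + ... + b_PC10 * PC10_i .

Sign convention: dates enter as years BP (positive = older), so a score that
*declines toward the present* has a **positive** ``date_bp`` coefficient.  All
one-sided tests here are expressed in terms of that decline ("decrease" side).

Because residual overdispersion makes the model-based standard errors
anticonservative, inference on the date term uses a genome-wide empirical
null: the same regression rerun on scores built from random SNP sets
frequency-matched (+-1%) to the trait panel, keeping the trait effect sizes as
weights.

The per-SNP model regresses presence/absence of the allele on date and the
PCs only (no latitude/longitude), with nested likelihood-ratio tests giving a
date p-value (1 df) and an ancestry p-value (one df per PC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import MISSING, GenotypeMatrix
from .glm import RegressionResult, _irls_batch, fit_binomial_logit
from .scores import _score_arrays, score_matrix
from .snp_sets import match_frequency

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("date_bp", "lat", "lon")


@dataclass
class EmpiricalTest:
    """Observed date coefficient against its genomic null distribution."""

    observed_beta_date: float
    null_betas: np.ndarray
    p_empirical: float
    b: int
    side: str = "decrease"

    @property
    def p_report(self) -> str:
        """Printed form; an observation beyond every null reports a bound."""
        if self.p_empirical <= 1.0 / (self.b + 1):
            return f"P < {1.0 / self.b:g}"
        return f"P = {self.p_empirical:g}"

    def as_dict(self) -> dict:
        return {
            "observed_beta_date": self.observed_beta_date,
            "p_empirical": self.p_empirical, "b": self.b, "side": self.side,
            "p_report": self.p_report,
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    meta: pd.DataFrame, pcs: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES, sample_ids=None,
):
    """Assemble (sample_ids, X, terms) with an intercept column first."""
    table = meta
    if pcs is not None:
        table = table.merge(pcs, on="sample_id", how="inner")
    if sample_ids is not None:
        table = table[table["sample_id"].isin(set(sample_ids))]
    terms = ["intercept"] + list(covariates)
    if pcs is not None:
        terms += [c for c in pcs.columns if c.startswith("pc")]
    X = np.column_stack(
        [np.ones(len(table))] + [table[t].to_numpy(float) for t in terms[1:]]
    )
    return table["sample_id"].tolist(), X, terms


def fit_score_glm(
    score_records: pd.DataFrame,
    meta: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES,
) -> RegressionResult:
    """Fit the binomial-logit score model by IRLS.

    ``score_records`` is the output of :func:`paleoscore.scores.score_matrix`;
    fractional successes m_i S_i are handled natively.
    """
    ids, X, terms = build_design(meta, pcs, covariates, score_records["sample_id"])
    rec = score_records.set_index("sample_id").loc[ids]
    m = rec["m"].to_numpy(float)
    s = rec["score"].to_numpy(float) * m
    return fit_binomial_logit(X, s, m, terms=terms)


# ---------------------------------------------------------------------------
# empirical genomic null
# ---------------------------------------------------------------------------

def _null_beta_dates(
    matrix, effect_table, pool, draws, X, row_index, date_col, chunk=500
):
    """Date coefficients for pre-drawn matched null SNP sets (batched IRLS)."""
    col_of = {s: j for j, s in enumerate(matrix.snp_ids)}
    pool_cols = np.array([col_of[s] for s in pool["snp_id"]])
    betas_w = effect_table["beta"].to_numpy(float)
    out = np.empty(len(draws))
    ok = np.empty(len(draws), dtype=bool)
    calls = matrix.calls
    for start in range(0, len(draws), chunk):
        idx = draws[start : start + chunk]
        block = calls[:, pool_cols[idx]]            # (n_all, b, M)
        block = block[row_index]                    # rows aligned with X
        observed = block != MISSING
        d = np.where(observed, block, 0).astype(float)
        w = betas_w[None, None, :]
        s = np.einsum("nbm,nbm->bn", d, np.broadcast_to(w, d.shape))
        m = np.einsum("nbm->bn", observed * w)
        beta, _, conv, _ = _irls_batch(X, s, m)
        out[start : start + len(idx)] = beta[:, date_col]
        ok[start : start + len(idx)] = conv
    return out, ok


def empirical_null_pvalue(
    matrix: GenotypeMatrix,
    effect_table: pd.DataFrame,
    meta: pd.DataFrame,
    pcs: pd.DataFrame | None,
    pool: pd.DataFrame,
    b: int = 10_000,
    tolerance: float = 0.01,
    seed=0,
    side: str = "decrease",
    covariates=DEFAULT_COVARIATES,
    weighted: bool = True,
    match_fallback: int = 0,
) -> EmpiricalTest:
    """Empirical p-value for the date term from frequency-matched null scores.

    ``pool`` is a DataFrame (snp_id, freq) of genome-wide SNPs present in
    ``matrix``, excluding the trait panel; each of ``b`` replicates substitutes
    every trait SNP by a pool SNP matched on effect-allele frequency within
    ``tolerance``, keeps the trait betas as weights, rebuilds scores and refits
    the identical model.

    ``side='decrease'`` (default) tests the hypothesis that the score declines
    toward the present (positive date-BP coefficient); ``'increase'`` and
    ``'two_sided'`` are available.  Replicates that fail to converge are
    dropped (error if more than 1% do).
    """
    if b < 100:
        raise ValueError("need at least 100 null replicates")
    overlap = set(pool["snp_id"]) & set(effect_table["snp_id"])
    if overlap:
        raise ValueError(f"pool must exclude trait SNPs; found {sorted(overlap)[:5]}")

    records = score_matrix(matrix, effect_table, weighted=weighted)
    observed = fit_score_glm(records, meta, pcs, covariates)
    beta_obs = observed.coef("date_bp")

    draws = match_frequency(
        effect_table["freq"].to_numpy(float), pool["freq"].to_numpy(float),
        n_sets=b, seed=seed, tolerance=tolerance, fallback_nearest=match_fallback,
    )
    ids, X, terms = build_design(meta, pcs, covariates, records["sample_id"])
    row_of = {s: i for i, s in enumerate(matrix.samples)}
    row_index = np.array([row_of[s] for s in ids])
    null_betas, ok = _null_beta_dates(
        matrix, effect_table, pool, draws, X, row_index, terms.index("date_bp")
    )
    n_fail = int((~ok).sum())
    if n_fail > 0.01 * b:
        raise RuntimeError(f"{n_fail}/{b} null replicate fits failed to converge")
    if n_fail:
        logger.warning("dropped %d non-converged null replicates", n_fail)
    null_betas = null_betas[ok]

    p = _one_sided_p(beta_obs, null_betas, side)
    return EmpiricalTest(
        observed_beta_date=float(beta_obs), null_betas=null_betas,
        p_empirical=p, b=len(null_betas), side=side,
    )


def _one_sided_p(obs, null, side):
    null = np.asarray(null, float)
    if side == "decrease":       # decline toward present = positive BP slope
        extreme = (null >= obs).sum()
    elif side == "increase":
        extreme = (null <= obs).sum()
    elif side == "two_sided":
        extreme = (np.abs(null) >= abs(obs)).sum()
    else:
        raise ValueError(f"unknown side {side!r}")
    return float((1 + extreme) / (len(null) + 1))


# ---------------------------------------------------------------------------
# ancestry stratification
# ---------------------------------------------------------------------------

GROUPS = ("hunter_gatherer", "early_farmer", "steppe")


def assign_ancestry_group(q: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Mutually exclusive ancestry groups from ADMIXTURE-style fractions.

    ``q`` columns: sample_id, hunter_gatherer, early_farmer, steppe (rows sum
    to 1).  Rules: hunter-gatherer if that component exceeds 60%; Steppe if the
    Steppe component exceeds 30% *and* the sample is younger than 5,000 BP
    (taking precedence over an Early Farmer component above 60%); Early Farmer
    if that component exceeds 60% and the Steppe rule does not fire; otherwise
    unassigned.  A sample satisfying both the hunter-gatherer and Steppe rules
    is labelled hunter-gatherer with a warning (the precedence of that conflict
    is not defined by the cutoffs).
    """
    total = q[list(GROUPS)].sum(axis=1)
    if (np.abs(total - 1) > 1e-6).any():
        bad = q.loc[np.abs(total - 1) > 1e-6, "sample_id"].tolist()
        raise ValueError(f"ancestry fractions do not sum to 1 for samples: {bad[:5]}")
    merged = q.merge(meta[["sample_id", "date_bp"]], on="sample_id")
    hg = merged["hunter_gatherer"] > 0.6
    steppe = (merged["steppe"] > 0.3) & (merged["date_bp"] < 5000)
    ef = merged["early_farmer"] > 0.6
    conflict = hg & steppe
    if conflict.any():
        logger.warning(
            "%d samples satisfy both hunter-gatherer and Steppe rules; "
            "labelled hunter_gatherer", int(conflict.sum()),
        )
    label = np.select(
        [hg, steppe, ef],
        ["hunter_gatherer", "steppe", "early_farmer"],
        default="unassigned",
    )
    return pd.Series(label, index=merged["sample_id"].to_numpy(), name="group")


def stratified_score_test(
    matrix: GenotypeMatrix,
    effect_table: pd.DataFrame,
    meta: pd.DataFrame,
    pcs: pd.DataFrame | None,
    groups: pd.Series,
    pool: pd.DataFrame,
    b: int = 1000,
    seed=0,
    min_group_size: int = 20,
    covariates=DEFAULT_COVARIATES,
    weighted: bool = True,
    match_fallback: int = 0,
) -> dict:
    """Within-group score-decline tests plus pairwise slope comparisons.

    Each sufficiently large ancestry group gets its own empirical-null test;
    slope differences are assessed through group x date interaction terms in a
    pooled model, with the interaction's null distribution built by refitting
    on the same frequency-matched null SNP sets.  Undersized groups are
    skipped (recorded in ``skipped``).
    """
    rng = np.random.default_rng(seed)
    records = score_matrix(matrix, effect_table, weighted=weighted)
    meta_g = meta.merge(groups.rename("group"), left_on="sample_id", right_index=True)

    per_group, skipped = {}, []
    for g in GROUPS:
        sub = meta_g[meta_g["group"] == g]
        if len(sub) < min_group_size:
            skipped.append(g)
            logger.warning("group %s has %d samples (< %d); skipped", g, len(sub), min_group_size)
            continue
        per_group[g] = empirical_null_pvalue(
            matrix, effect_table, sub, pcs, pool, b=b, seed=int(rng.integers(2**31)),
            covariates=covariates, weighted=weighted, match_fallback=match_fallback,
        )

    # pooled interaction model over the assigned groups
    tested = [g for g in GROUPS if g not in skipped]
    pooled = meta_g[meta_g["group"].isin(tested)].copy()
    ids, X, terms = build_design(pooled, pcs, covariates, records["sample_id"])
    pooled = pooled.set_index("sample_id").loc[ids].reset_index()
    extra_terms, extra_cols = [], []
    for g in tested[1:]:
        dummy = (pooled["group"] == g).to_numpy(float)
        extra_terms += [f"group_{g}", f"date_x_{g}"]
        extra_cols += [dummy, dummy * pooled["date_bp"].to_numpy(float)]
    X = np.column_stack([X] + extra_cols)
    terms = terms + extra_terms

    rec = records.set_index("sample_id").loc[ids]
    m = rec["m"].to_numpy(float)
    s = rec["score"].to_numpy(float) * m
    full = fit_binomial_logit(X, s, m, terms=terms)

    # empirical null for each interaction contrast
    draws = match_frequency(
        effect_table["freq"].to_numpy(float), pool["freq"].to_numpy(float),
        n_sets=b, seed=int(rng.integers(2**31)), tolerance=0.01,
        fallback_nearest=match_fallback,
    )
    row_of = {smp: i for i, smp in enumerate(matrix.samples)}
    row_index = np.array([row_of[smp] for smp in ids])
    pairwise = []
    base = tested[0]
    null_cache = {}
    for g in tested[1:]:
        col = terms.index(f"date_x_{g}")
        if col not in null_cache:
            null_cache[col], _ = _null_beta_dates(
                matrix, effect_table, pool, draws, X, row_index, col
            )
        obs = full.params[col]
        p = _one_sided_p(obs, null_cache[col], "two_sided")
        pairwise.append(
            {"group_a": base, "group_b": g, "slope_difference": float(obs), "p_empirical": p}
        )
    return {
        "per_group": per_group, "pooled_fit": full,
        "pairwise": pd.DataFrame(pairwise), "skipped": skipped,
    }


# ---------------------------------------------------------------------------
# leave-top-k attenuation
# ---------------------------------------------------------------------------

def leave_top_k(
    matrix: GenotypeMatrix,
    effect_table: pd.DataFrame,
    k_list,
    meta: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    pool: pd.DataFrame | None = None,
    b: int = 0,
    seed=0,
    covariates=DEFAULT_COVARIATES,
    match_fallback: int = 0,
) -> pd.DataFrame:
    """Refit the score model with the top-k largest-|beta| SNPs removed.

    Attenuation is 100 * (beta_full - beta_k) / beta_full, the percentage of
    the full-panel date effect lost by dropping the k largest effects.  If a
    ``pool`` is given and ``b`` > 0, each k also gets an empirical p-value.
    """
    ranked = effect_table.reindex(
        effect_table["beta"].abs().sort_values(ascending=False, kind="mergesort").index
    ).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    rows = []
    beta_full = None
    for k in sorted({0} | {int(k) for k in k_list}):
        if k >= len(ranked):
            raise ValueError(f"k={k} must be smaller than the panel size {len(ranked)}")
        panel = ranked.iloc[k:]
        records = score_matrix(matrix, panel, weighted=True)
        fit = fit_score_glm(records, meta, pcs, covariates)
        beta_k = fit.coef("date_bp")
        if beta_full is None and k == 0:
            beta_full = beta_k
        row = {"k": k, "beta_date": beta_k, "n_snps": len(panel), "converged": fit.converged}
        if beta_full is not None:
            row["attenuation_pct"] = 100.0 * (beta_full - beta_k) / beta_full
        if pool is not None and b > 0:
            test = empirical_null_pvalue(
                matrix, panel, meta, pcs,
                pool[~pool["snp_id"].isin(panel["snp_id"])],
                b=b, seed=int(rng.integers(2**31)), covariates=covariates,
                match_fallback=match_fallback,
            )
            row["p_empirical"] = test.p_empirical
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-SNP regressions and likelihood-ratio tests
# ---------------------------------------------------------------------------

SNP_COVARIATES = ("date_bp",)  # per-SNP model: date + PCs, no lat/lon


def snp_logistic(
    matrix: GenotypeMatrix,
    snp_id: str,
    meta: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    min_samples: int = 30,
) -> RegressionResult | None:
    """Bernoulli logistic fit of one SNP's allele presence on date and PCs.

    Returns None for monomorphic SNPs or insufficient non-missing samples
    (logged with a code).  Latitude/longitude are deliberately absent from
    this model.
    """
    j = matrix.snp_ids.index(snp_id)
    calls = matrix.calls[:, j]
    called = pd.DataFrame({"sample_id": matrix.samples, "y": calls})
    called = called[called["y"] != MISSING]
    ids, X, terms = build_design(meta, pcs, SNP_COVARIATES, called["sample_id"])
    y = called.set_index("sample_id").loc[ids, "y"].to_numpy(float)
    if len(y) < min_samples:
        logger.info("SNP %s skipped: only %d non-missing samples", snp_id, len(y))
        return None
    if y.min() == y.max():
        logger.info("SNP %s skipped: monomorphic", snp_id)
        return None
    return fit_binomial_logit(X, y, np.ones_like(y), terms=terms)


def lrt(full: RegressionResult, nested: RegressionResult, df: int | None = None) -> float:
    """Likelihood-ratio p-value for nested binomial-logit fits.

    df defaults to the difference in parameter count (10 for the PC block,
    1 for the date term).  A full-model likelihood below the nested one (beyond
    rounding) indicates a fit failure and raises.
    """
    if not set(nested.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    if full.n_samples != nested.n_samples:
        raise ValueError("nested comparison requires identical samples")
    stat = 2.0 * (full.llf - nested.llf)
    if stat < -1e-6:
        raise ValueError(f"full model log-likelihood below nested ({stat/2:.3g}); fit failure")
    if df is None:
        df = len(full.terms) - len(nested.terms)
    return float(stats.chi2.sf(max(stat, 0.0), df))


def per_snp_scan(
    matrix: GenotypeMatrix,
    snp_ids,
    meta: pd.DataFrame,
    pcs: pd.DataFrame | None,
    min_samples: int = 30,
) -> pd.DataFrame:
    """Date and ancestry LRT p-values for each SNP in ``snp_ids``.

    For each SNP, the full model (date + PCs) is compared against nested models
    without the PC block (ancestry test) and without the date term (date test).
    Skipped SNPs carry a ``skip`` code instead of estimates.
    """
    if pcs is not None:  # identical samples across full and nested fits
        meta = meta[meta["sample_id"].isin(set(pcs["sample_id"]))]
    rows = []
    for snp_id in snp_ids:
        full = snp_logistic(matrix, snp_id, meta, pcs, min_samples)
        if full is None:
            rows.append({"snp_id": snp_id, "skip": "monomorphic_or_undersized"})
            continue
        j = matrix.snp_ids.index(snp_id)
        calls = matrix.calls[:, j]
        called_ids = [s for s, c in zip(matrix.samples, calls) if c != MISSING]
        sub_meta = meta[meta["sample_id"].isin(called_ids)]
        no_date = _fit_subset(matrix, snp_id, sub_meta, pcs, covariates=())
        no_pcs = _fit_subset(matrix, snp_id, sub_meta, None, covariates=SNP_COVARIATES)
        rows.append(
            {
                "snp_id": snp_id, "skip": "",
                "beta_date": full.coef("date_bp"),
                "se_date": full.se("date_bp"),
                "p_date": lrt(full, no_date, df=1),
                "p_ancestry": lrt(full, no_pcs) if pcs is not None else np.nan,
                "n": full.n_samples,
                "converged": full.converged,
            }
        )
    return pd.DataFrame(rows)


def _fit_subset(matrix, snp_id, meta, pcs, covariates):
    j = matrix.snp_ids.index(snp_id)
    calls = matrix.calls[:, j]
    called = pd.DataFrame({"sample_id": matrix.samples, "y": calls})
    called = called[called["y"] != MISSING]
    ids, X, terms = build_design(meta, pcs, covariates, called["sample_id"])
    y = called.set_index("sample_id").loc[ids, "y"].to_numpy(float)
    return fit_binomial_logit(X, y, np.ones_like(y), terms=terms)


def effect_vs_change_regression(effect_table: pd.DataFrame, per_snp: pd.DataFrame) -> dict:
    """OLS of |per-SNP date coefficient| on |GWAS effect size|.

    Tests whether SNPs with larger effects changed more in frequency over
    time; returns slope, adjusted R-squared and the slope p-value.
    Non-converged per-SNP fits (quasi-separation inflates their date
    coefficients arbitrarily) are excluded.
    """
    import statsmodels.api as sm

    usable = per_snp[per_snp["skip"] == ""]
    if "converged" in usable.columns:
        usable = usable[usable["converged"].astype(bool)]
    merged = effect_table.merge(usable, on="snp_id")
    if len(merged) < 3:
        raise ValueError(f"need at least 3 SNPs with estimates, have {len(merged)}")
    y = merged["beta_date"].abs().to_numpy(float)
    x = sm.add_constant(merged["beta"].abs().to_numpy(float))
    fit = sm.OLS(y, x).fit()
    return {
        "slope": float(fit.params[1]), "adj_r2": float(fit.rsquared_adj),
        "p_slope": float(fit.pvalues[1]), "n_snps": len(merged),
    }
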