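"""Closed-form per-SNP variance-explained decompositions.

For a SNP with effect size beta and allele frequency f in a population, the
phenotypic variance it explains within that population is 2 beta^2 f(1-f).
The proportion of variance explained additionally uses the GWAS sampling noise
(standard error sigma at sample size N); the between-population term contrasts
two frequencies f1, f2 through f_avg = (f1 + f2)/2.  All three quantities are
invariant to the sign of beta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_freq(name, f):
    f = np.asarray(f, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return f


def ve_within(beta, f):
    """Variance explained within a population: 2 beta^2 f (1 - f)."""
    f = _check_freq("f", f)
    out = 2.0 * np.asarray(beta, float) ** 2 * f * (1.0 - f)
    return out if out.ndim else float(out)


def pve_within(beta, f, sigma, n):
    """Proportion of within-population variance explained.

    PVE = VE / (VE + 2 N sigma^2 f (1-f)) with N the GWAS sample size and
    sigma the standard error of beta.  Tends to 1 as sigma -> 0 and to 0 as
    sigma -> infinity.
    """
    f = _check_freq("f", f)
    sigma = np.asarray(sigma, float)
    if (sigma <= 0).any():
        raise ValueError("sigma must be positive")
    if np.any(np.asarray(n) < 1):
        raise ValueError("N must be >= 1")
    ve = ve_within(beta, f)
    den = ve + 2.0 * np.asarray(n, float) * sigma**2 * f * (1.0 - f)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, ve / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def ve_between(beta, f1, f2):
    """Variance explained between two populations.

    beta^2 ( f_avg (1 - f_avg) - [f1(1-f1) + f2(1-f2)] / 2 ) with
    f_avg = (f1 + f2)/2; zero when f1 = f2 and non-negative everywhere
    (concavity of f(1-f)).
    """
    f1 = _check_freq("f1", f1)
    f2 = _check_freq("f2", f2)
    favg = 0.5 * (f1 + f2)
    out = np.asarray(beta, float) ** 2 * (
        favg * (1.0 - favg) - 0.5 * (f1 * (1.0 - f1) + f2 * (1.0 - f2))
    )
    return out if out.ndim else float(out)


def ve_table(
    effect_table: pd.DataFrame,
    f_within: str = "freq",
    f_pop1: str | None = None,
    f_pop2: str | None = None,
    gwas_n: float = 356_530,
) -> pd.DataFrame:
    """Per-SNP decomposition table for a dark-oriented effect panel.

    ``f_within`` names the within-population frequency column; ``f_pop1`` /
    ``f_pop2`` (optional) name the two columns contrasted for the
    between-population term.  The default N is a UK-Biobank-scale GWAS size.
    """
    out = effect_table[["snp_id", "beta", "se"]].copy()
    f = effect_table[f_within].to_numpy(float)
    out["f"] = f
    out["ve_within"] = ve_within(out["beta"], f)
    out["pve_within"] = pve_within(out["beta"], f, out["se"], gwas_n)
    if f_pop1 and f_pop2:
        f1 = effect_table[f_pop1].to_numpy(float)
        f2 = effect_table[f_pop2].to_numpy(float)
        out["f1"], out["f2"] = f1, f2
        out["ve_between"] = ve_between(out["beta"], f1, f2)
    out["gwas_n"] = gwas_n
    return out
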