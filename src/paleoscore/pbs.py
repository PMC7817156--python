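"""Windowed Hudson FST and the population branch statistic (PBS).

For a focal population X and two outgroups O1, O2, pairwise FST is estimated
with Hudson's sample-size-corrected estimator,

    FST = [ (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) ]
          / [ p1(1-p2) + p2(1-p1) ],

converted to branch lengths T = -ln(1 - FST), and combined per window as

    PBS_X = (T_X,O1 + T_X,O2 - T_O1,O2) / 2 ,

which localizes allele-frequency differentiation to the X lineage.  Windows
are nonoverlapping runs of 20 (or 40) consecutive SNPs within a chromosome,
after excluding SNPs with missing rate above 90%; window FST is the ratio of
summed numerators over summed denominators (the standard aggregation for
Hudson-type estimators).  Negative FST (and hence negative T) is retained so
genome-wide percentiles stay honest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column names expected in a frequency table
FREQ_COLUMNS = ("snp_id", "chrom", "pos")


def hudson_fst_components(p1, p2, n1, n2):
    """Per-SNP numerator and denominator of Hudson's FST estimator.

    SNPs where the denominator is 0 (both populations fixed for the same
    allele) are non-informative; callers exclude them from window sums.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    if (n1 <= 1).any() or (n2 <= 1).any():
        raise ValueError("sample sizes must exceed 1 (estimator divides by n-1)")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(p1, p2, n1, n2):
    """Hudson FST per SNP; NaN where non-informative (may be negative)."""
    num, den = hudson_fst_components(p1, p2, n1, n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def t_divergence(fst):
    """Branch-length transform T = -ln(1 - FST); FST = 1 is capped and flagged."""
    fst = np.asarray(fst, dtype=float)
    capped = fst >= 1.0
    if capped.any():
        logger.warning("%d windows with FST >= 1; T capped", int(capped.sum()))
    safe = np.where(capped, 1.0 - 1e-12, fst)
    out = -np.log1p(-safe)
    return out if out.ndim else float(out)


def window_fst(
    freq: pd.DataFrame,
    pair: tuple[str, str],
    window_size: int = 20,
    max_missing_rate: float = 0.9,
) -> pd.DataFrame:
    """Per-window Hudson FST (ratio of sums) for one population pair.

    ``freq`` columns: snp_id, chrom, pos, p_<pop>, n_<pop> per population and
    optionally ``missing_rate``.  SNPs with missing rate above the cutoff are
    excluded before windowing; windows are consecutive retained SNPs within a
    chromosome, trailing incomplete windows dropped.
    """
    a, b = pair
    table = freq
    if "missing_rate" in table.columns:
        table = table[table["missing_rate"] <= max_missing_rate]
    table = table.sort_values(["chrom", "pos"], kind="mergesort")

    rows = []
    for chrom, grp in table.groupby("chrom", sort=False):
        n_win = len(grp) // window_size
        if n_win == 0:
            logger.info("chromosome %s: %d retained SNPs < window size %d; no windows",
                        chrom, len(grp), window_size)
            continue
        num, den = hudson_fst_components(
            grp[f"p_{a}"].to_numpy(), grp[f"p_{b}"].to_numpy(),
            grp[f"n_{a}"].to_numpy(), grp[f"n_{b}"].to_numpy(),
        )
        informative = den > 0
        ids = grp["snp_id"].to_numpy()
        for w in range(n_win):
            sl = slice(w * window_size, (w + 1) * window_size)
            inf = informative[sl]
            den_sum = den[sl][inf].sum()
            fst = num[sl][inf].sum() / den_sum if den_sum > 0 else np.nan
            rows.append(
                {
                    "chrom": chrom, "window": w, "snp_ids": ",".join(ids[sl]),
                    "n_informative": int(inf.sum()), f"fst_{a}_{b}": fst,
                }
            )
    return pd.DataFrame(rows)


def pbs_windows(
    freq: pd.DataFrame,
    focal: str,
    outgroup1: str,
    outgroup2: str,
    window_size: int = 20,
    max_missing_rate: float = 0.9,
) -> pd.DataFrame:
    """Windowed PBS for ``focal`` against two outgroups.

    Returns one row per window with the three pairwise FSTs, T values and PBS
    for all three branches (focal and both outgroups).
    """
    pairs = [(focal, outgroup1), (focal, outgroup2), (outgroup1, outgroup2)]
    tracks = [
        window_fst(freq, pr, window_size=window_size, max_missing_rate=max_missing_rate)
        for pr in pairs
    ]
    base = tracks[0][["chrom", "window", "snp_ids", "n_informative"]]
    for t in tracks[1:]:
        if not (t["chrom"].equals(tracks[0]["chrom"]) and t["window"].equals(tracks[0]["window"])):
            raise ValueError("window tracks misaligned across population pairs")
    out = base.copy()
    t_vals = []
    for (a, b), track in zip(pairs, tracks):
        out[f"fst_{a}_{b}"] = track[f"fst_{a}_{b}"].to_numpy()
        tt = t_divergence(out[f"fst_{a}_{b}"].to_numpy())
        out[f"T_{a}_{b}"] = tt
        t_vals.append(tt)
    t_x1, t_x2, t_12 = t_vals
    out[f"pbs_{focal}"] = (t_x1 + t_x2 - t_12) / 2.0
    out[f"pbs_{outgroup1}"] = (t_x1 + t_12 - t_x2) / 2.0
    out[f"pbs_{outgroup2}"] = (t_x2 + t_12 - t_x1) / 2.0
    return out


def percentile_flags(
    window_stats: pd.DataFrame,
    pbs_column: str,
    trait_snp_ids=(),
    thresholds=(0.01, 0.001),
    window_size: int | None = None,
) -> pd.DataFrame:
    """Annotate windows with genome-wide PBS percentile ranks and trait flags.

    ``top_fraction`` is the fraction of windows with PBS at least as large
    (1/N for the maximum).  A window is flagged ``contains_trait`` if any trait
    SNP is a member and ``centered_on_trait`` if a trait SNP is the
    ceil(size/2)-th member.  Threshold columns ``top_<q>`` mark membership in
    the top q fraction.
    """
    out = window_stats.copy()
    pbs = out[pbs_column].to_numpy(float)
    n = len(out)
    if n < 1000:
        logger.warning("only %d windows; percentile ranks are unstable below ~1,000", n)
    order = (-pbs).argsort(kind="mergesort")
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(1, n + 1)
    out["top_fraction"] = rank / n

    trait = set(trait_snp_ids)
    members = out["snp_ids"].str.split(",")
    out["contains_trait"] = [bool(trait & set(m)) for m in members]
    center = None
    out["centered_on_trait"] = False
    if window_size:
        center = int(np.ceil(window_size / 2)) - 1
        out["centered_on_trait"] = [
            len(m) > center and m[center] in trait for m in members
        ]
    for q in thresholds:
        out[f"top_{q:g}"] = out["top_fraction"] <= q
    return out
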