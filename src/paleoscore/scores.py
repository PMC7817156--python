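"""Per-individual genetic scores for pseudohaploid data.

Because coverage varies wildly across ancient samples, scores are proportions
over the SNPs actually genotyped in each individual.  With dark-oriented
effects (all beta >= 0) and pseudohaploid carriage d_i in {0, 1}:

    weighted score   = sum(d_i * beta_i) / sum(beta_i)   over genotyped SNPs
    unweighted score = mean(d_i)                         over genotyped SNPs

The weighted form divides the realized score by the maximum possible score
given the SNPs present, so both scores live in [0, 1] regardless of
missingness.  Individuals with no genotyped panel SNP are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def _score_arrays(calls: np.ndarray, betas: np.ndarray, weighted: bool):
    """Vectorized scores for a (samples x panel SNPs) call block.

    Returns (m, score) with score NaN where m == 0.
    """
    if (betas < 0).any():
        raise ValueError("negative beta: effect table must be dark-oriented first")
    observed = calls != MISSING
    d = np.where(observed, calls, 0).astype(float)
    m = observed.sum(axis=1)
    w = betas if weighted else np.ones_like(betas, dtype=float)
    num = d @ w
    den = observed @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return m, np.clip(score, 0.0, 1.0)  # clip float rounding at the boundaries


def score_matrix(
    matrix: GenotypeMatrix, effect_table: pd.DataFrame, weighted: bool = True
) -> pd.DataFrame:
    """Score every sample against a trait-SNP panel.

    Returns a DataFrame with columns ``sample_id, m, score, weighted`` holding
    one row per sample with at least one genotyped panel SNP.  Panel SNPs not
    present in the matrix are dropped (logged); zero overlap is an error.
    """
    ids = {s: j for j, s in enumerate(matrix.snp_ids)}
    found = effect_table[effect_table["snp_id"].isin(ids)]
    n_missing = len(effect_table) - len(found)
    if found.empty:
        raise ValueError("no effect-table SNP present in the genotype matrix")
    if n_missing:
        logger.info(
            "score panel: %d/%d SNPs found in matrix (%d absent)",
            len(found), len(effect_table), n_missing,
        )
    cols = [ids[s] for s in found["snp_id"]]
    m, score = _score_arrays(
        matrix.calls[:, cols], found["beta"].to_numpy(float), weighted
    )
    out = pd.DataFrame(
        {"sample_id": matrix.samples, "m": m, "score": score, "weighted": weighted}
    )
    dropped = out[out["m"] == 0]
    if len(dropped):
        logger.info("excluded %d samples with no genotyped panel SNP", len(dropped))
    return out[out["m"] > 0].reset_index(drop=True)


def weighted_score(calls_for_individual, effect_table: pd.DataFrame) -> dict:
    """Weighted score of one individual; ``calls`` aligned with the table rows."""
    calls = np.asarray(calls_for_individual, dtype=float)[None, :]
    m, score = _score_arrays(calls, effect_table["beta"].to_numpy(float), weighted=True)
    if m[0] == 0:
        raise ValueError("individual has no genotyped panel SNP")
    return {"m": int(m[0]), "score": float(score[0]), "weighted": True}


def unweighted_score(calls_for_individual, snp_panel) -> dict:
    """Unweighted (equal-weight) score of one individual."""
    calls = np.asarray(calls_for_individual, dtype=float)[None, :]
    m, score = _score_arrays(calls, np.ones(calls.shape[1]), weighted=False)
    if m[0] == 0:
        raise ValueError("individual has no genotyped panel SNP")
    return {"m": int(m[0]), "score": float(score[0]), "weighted": False}


def write_scores(records: pd.DataFrame, path):
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")
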