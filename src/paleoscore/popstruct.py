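"""Ancestry covariates: genotype PCA on a reference panel with least-squares
projection of incomplete pseudohaploid samples.

The reference panel (assumed complete, or mean-imputed) defines the axes;
ancient samples, which can be missing most sites, are then projected by
restricting the loadings to each sample's called sites and solving a small
least-squares problem.  Sites are centered by their reference mean dosage and
scaled by sqrt(f(1-f)), the standard genotype-PCA normalization.  Component
signs are fixed (largest-magnitude loading positive) so runs are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCModel:
    snp_ids: list[str]
    mean: np.ndarray          # per-SNP reference mean dosage
    scale: np.ndarray         # per-SNP sqrt(f(1-f))
    loadings: np.ndarray      # (n_snps, K), orthonormal columns
    explained_var: np.ndarray  # fraction of variance per component
    ploidy: int = 1

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "snp_ids": self.snp_ids,
                    "mean": self.mean.tolist(),
                    "scale": self.scale.tolist(),
                    "loadings": self.loadings.tolist(),
                    "explained_var": self.explained_var.tolist(),
                    "ploidy": self.ploidy,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            snp_ids=d["snp_ids"], mean=np.array(d["mean"]), scale=np.array(d["scale"]),
            loadings=np.array(d["loadings"]), explained_var=np.array(d["explained_var"]),
            ploidy=d["ploidy"],
        )


def fit_reference_pca(reference: GenotypeMatrix, k: int = 10) -> PCModel:
    """Fit a K-component genotype PCA on a complete reference panel.

    Missing reference calls are mean-imputed (after a warning); constant SNPs
    are dropped.
    """
    calls = reference.calls.astype(float)
    miss = calls == MISSING
    calls[miss] = np.nan
    mean = np.nanmean(calls, axis=0)
    if miss.any():
        logger.warning(
            "reference panel has %.2f%% missing calls; mean-imputed",
            100 * miss.mean(),
        )
        calls = np.where(miss, mean[None, :], calls)
    f = mean / reference.ploidy
    keep = (f > 0) & (f < 1)
    if not keep.all():
        logger.warning("dropping %d constant SNPs from PCA", int((~keep).sum()))
    calls, mean, f = calls[:, keep], mean[keep], f[keep]
    snp_ids = [s for s, k_ in zip(reference.snp_ids, keep) if k_]

    k = min(k, calls.shape[0] - 1, calls.shape[1])
    scale = np.sqrt(f * (1.0 - f))
    z = (calls - mean[None, :]) / scale[None, :]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    total = float((s**2).sum())
    loadings = vt[:k].T
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return PCModel(
        snp_ids=snp_ids, mean=mean, scale=scale, loadings=loadings,
        explained_var=(s[:k] ** 2) / total, ploidy=reference.ploidy,
    )


def pca_scores(model: PCModel, reference: GenotypeMatrix) -> pd.DataFrame:
    """Coordinates of complete samples (the fitted scores for the reference)."""
    return project_samples(model, reference, min_overlap=0.0)


def project_samples(
    model: PCModel, matrix: GenotypeMatrix, min_overlap: float = 0.1
) -> pd.DataFrame:
    """Project (possibly very incomplete) samples onto reference PCs.

    For each sample the loadings are restricted to its non-missing model SNPs
    and its standardized calls regressed on them (least squares).  Samples
    covering fewer than ``min_overlap`` of the model SNPs are excluded.

    Returns a DataFrame ``sample_id, pc1..pcK`` (excluded samples absent;
    exclusions logged).
    """
    cols = {s: j for j, s in enumerate(matrix.snp_ids)}
    present = [j for j, s in enumerate(model.snp_ids) if s in cols]
    if not present:
        raise ValueError("no model SNP present in the sample matrix")
    mat_cols = [cols[model.snp_ids[j]] for j in present]
    calls = matrix.calls[:, mat_cols].astype(float)
    calls[calls == MISSING] = np.nan
    if matrix.ploidy != model.ploidy:
        calls *= model.ploidy / matrix.ploidy  # dosage scale alignment

    mean = model.mean[present]
    scale = model.scale[present]
    load = model.loadings[present, :]

    rows, ids = [], []
    n_model = len(model.snp_ids)
    for i, sid in enumerate(matrix.samples):
        obs = ~np.isnan(calls[i])
        if obs.sum() < max(min_overlap * n_model, 1):
            logger.info("sample %s excluded from projection: %d/%d model SNPs called",
                        sid, int(obs.sum()), n_model)
            continue
        z = (calls[i, obs] - mean[obs]) / scale[obs]
        coord, *_ = np.linalg.lstsq(load[obs, :], z, rcond=None)
        rows.append(coord)
        ids.append(sid)
    if not rows:
        return pd.DataFrame(columns=["sample_id"] + [f"pc{j+1}" for j in range(model.k)])
    out = pd.DataFrame(np.array(rows), columns=[f"pc{j+1}" for j in range(model.k)])
    out.insert(0, "sample_id", ids)
    return out
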