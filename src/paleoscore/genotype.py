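"""Pseudohaploid genotype containers, EIGENSTRAT/VCF input and sample-level QC.

Ancient-DNA datasets are commonly distributed as EIGENSTRAT triplets
(``.geno``/``.snp``/``.ind``) with one pseudohaploid call per site: because most
ancient samples are low coverage, a single allele is sampled per site instead of
a diploid genotype.  This module provides the in-memory container
(:class:`GenotypeMatrix`), lossless EIGENSTRAT round-tripping, diploid VCF input,
random-allele pseudohaploidization, and the standard sample filters: a minimum
fold-coverage cutoff, a geographic window, and identity-by-state (IBS) duplicate
detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1
"""Internal missing-call code (EIGENSTRAT files use ``9``)."""

#: Columns required in a sample-metadata table (on disk the id column may be
#: named ``id``; in memory the package standard is ``sample_id``).
META_COLUMNS = ("sample_id", "date_bp", "lat", "lon", "coverage")

_VALID_ALLELES = frozenset("ACGT")


class EigenstratParseError(ValueError):
    """Structured parse failure naming the offending file and line."""

    def __init__(self, path, line, message):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}, line {line}: {message}")


@dataclass(frozen=True)
class SNPRecord:
    """Per-SNP identity carried through every analysis stage."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    dark_oriented: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele not in _VALID_ALLELES or self.alt_allele not in _VALID_ALLELES:
            raise ValueError(f"SNP {self.id}: alleles must be in ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt alleles are identical")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs call matrix.

    ``calls[i, j]`` is the number of alternate-allele copies carried by sample
    ``i`` at SNP ``j``: ``{0, 1}`` for pseudohaploid data, ``{0, 1, 2}`` for
    diploid data, :data:`MISSING` (``-1``) for no call.
    """

    samples: list[str]
    snps: list[SNPRecord]
    calls: np.ndarray
    ploidy: int = 1

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        allowed = {MISSING, 0, 1} if self.ploidy == 1 else {MISSING, 0, 1, 2}
        bad = set(np.unique(self.calls)) - allowed
        if bad:
            raise ValueError(f"invalid call codes for ploidy {self.ploidy}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def n_missing_per_sample(self) -> np.ndarray:
        return self.missing_mask().sum(axis=1)

    def missing_rate_per_snp(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls (NaN if none)."""
        calls = np.ma.masked_equal(self.calls, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-missing columns -> NaN
            freq = calls.mean(axis=0).filled(np.nan) / self.ploidy
        return np.asarray(freq, dtype=float)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in sample_ids]
        return replace(self, samples=list(sample_ids), calls=self.calls[rows, :])

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        index = {s.id: j for j, s in enumerate(self.snps)}
        cols = [index[s] for s in snp_ids]
        return replace(
            self, snps=[self.snps[j] for j in cols], calls=self.calls[:, cols]
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path, *, ploidy=1) -> GenotypeMatrix:
    """Read an EIGENSTRAT triplet.

    The ``.geno`` file holds one row per SNP and one digit per sample
    (alternate-allele count; ``9`` = missing).  ``ploidy=1`` expects
    pseudohaploid calls in ``{0, 1, 9}``; ``ploidy=2`` accepts ``{0, 1, 2, 9}``.

    Raises
    ------
    EigenstratParseError
        On any dimension mismatch or invalid character, naming file and line.
    """
    ind = _read_ind(ind_path)
    snps = _read_snp(snp_path)
    n_samples, n_snps = len(ind), len(snps)

    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    digit_max = ploidy
    with open(geno_path) as fh:
        row = -1
        for row, line in enumerate(fh):
            line = line.rstrip("\n")
            if row >= n_snps:
                raise EigenstratParseError(
                    geno_path, row + 1, f"more genotype rows than the {n_snps} SNPs in {snp_path}"
                )
            if len(line) != n_samples:
                raise EigenstratParseError(
                    geno_path, row + 1,
                    f"{len(line)} genotype columns but {n_samples} samples in {ind_path}",
                )
            vals = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            bad = (vals > digit_max) & (vals != 9)
            if bad.any():
                raise EigenstratParseError(
                    geno_path, row + 1, f"invalid genotype code {line[int(np.argmax(bad))]!r}"
                )
            out = vals.astype(np.int8)
            out[vals == 9] = MISSING
            calls[:, row] = out
    if row + 1 != n_snps:
        raise EigenstratParseError(
            geno_path, row + 2, f"expected {n_snps} genotype rows, found {row + 1}"
        )
    return GenotypeMatrix(samples=[s for s, _ in ind], snps=snps, calls=calls, ploidy=ploidy)


def _read_ind(path):
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if len(parts) < 3:
                raise EigenstratParseError(path, i + 1, "expected 'id sex label'")
            out.append((parts[0], parts[2]))
    return out


def _read_snp(path):
    snps = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if len(parts) < 6:
                raise EigenstratParseError(
                    path, i + 1, "expected 'id chrom genetic_pos pos ref alt'"
                )
            try:
                snps.append(
                    SNPRecord(
                        id=parts[0], chrom=parts[1], pos=int(parts[3]),
                        ref_allele=parts[4], alt_allele=parts[5],
                    )
                )
            except ValueError as exc:
                raise EigenstratParseError(path, i + 1, str(exc)) from exc
    return snps


def write_eigenstrat(matrix: GenotypeMatrix, geno_path, snp_path, ind_path, *, labels=None):
    """Write an EIGENSTRAT triplet; inverse of :func:`read_eigenstrat`."""
    labels = labels or {}
    with open(ind_path, "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s}\tU\t{labels.get(s, 'Sample')}\n")
    with open(snp_path, "w") as fh:
        for rec in matrix.snps:
            fh.write(
                f"{rec.id}\t{rec.chrom}\t0.0\t{rec.pos}\t{rec.ref_allele}\t{rec.alt_allele}\n"
            )
    codes = matrix.calls.T.astype(np.int16)  # SNP-major on disk
    codes[codes == MISSING] = 9
    digits = (codes + ord("0")).astype(np.uint8)
    with open(geno_path, "wb") as fh:
        newline = np.full((digits.shape[0], 1), ord("\n"), dtype=np.uint8)
        fh.write(np.hstack([digits, newline]).tobytes())


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF (``GT`` field; ``./.`` = missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snps, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic sites only
        snps.append(
            SNPRecord(
                id=var.ID or f"{var.CHROM}_{var.POS}", chrom=str(var.CHROM),
                pos=var.POS, ref_allele=var.REF, alt_allele=var.ALT[0],
            )
        )
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2 alt copies, 3=missing
        gt[gt == 3] = MISSING
        columns.append(gt)
    calls = np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls, ploidy=2)


# ---------------------------------------------------------------------------
# Pseudohaploidization
# ---------------------------------------------------------------------------

def pseudohaploidize(matrix: GenotypeMatrix, seed) -> GenotypeMatrix:
    """Collapse diploid calls to one randomly sampled allele per site.

    Homozygotes are deterministic (0 -> 0, 2 -> 1); heterozygotes draw a fair
    Bernoulli allele; missing stays missing.  Already-haploid input is returned
    unchanged (idempotence).
    """
    if matrix.ploidy == 1:
        return matrix
    rng = np.random.default_rng(seed)
    calls = matrix.calls
    bad = ~np.isin(calls, (MISSING, 0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid diploid code {calls[i, j]} at sample {matrix.samples[i]!r}, "
            f"SNP {matrix.snps[j].id!r}"
        )
    out = np.where(calls == 2, 1, calls).astype(np.int8)
    het = calls == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return replace(matrix, calls=out, ploidy=1)


# ---------------------------------------------------------------------------
# Sample metadata and filters
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> pd.DataFrame:
    """Read a sample-metadata TSV with columns id, date_bp, lat, lon, coverage.

    A header column named ``id`` is normalized to ``sample_id``.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"id": str, "sample_id": str})
    if "id" in meta.columns and "sample_id" not in meta.columns:
        meta = meta.rename(columns={"id": "sample_id"})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    validate_sample_meta(meta)
    return meta


def validate_sample_meta(meta: pd.DataFrame):
    if (meta["date_bp"] < 0).any():
        bad = meta.loc[meta["date_bp"] < 0, "sample_id"].tolist()
        raise ValueError(f"negative date_bp for samples: {bad}")
    if ((meta["lat"] < -90) | (meta["lat"] > 90)).any():
        bad = meta.loc[(meta["lat"] < -90) | (meta["lat"] > 90), "sample_id"].tolist()
        raise ValueError(f"latitude out of range for samples: {bad}")


def write_sample_meta(meta: pd.DataFrame, path):
    out = meta.rename(columns={"sample_id": "id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _id_column(meta: pd.DataFrame) -> str:
    return "sample_id" if "sample_id" in meta.columns else "id"


def filter_coverage(meta: pd.DataFrame, min_coverage: float = 0.1) -> list[str]:
    """Sample ids with fold-coverage >= ``min_coverage`` (default 0.1x).

    Samples at exactly the cutoff are retained: the exclusion rule is
    strictly-below-threshold.
    """
    idc = _id_column(meta)
    if "coverage" not in meta.columns or meta["coverage"].isna().any():
        bad = meta[idc].tolist() if "coverage" not in meta.columns else (
            meta.loc[meta["coverage"].isna(), idc].tolist()
        )
        raise ValueError(f"coverage missing for samples: {bad}")
    return meta.loc[meta["coverage"] >= min_coverage, idc].tolist()


def filter_geography(meta: pd.DataFrame, max_lon: float = 60.0, min_lat: float = 35.0) -> list[str]:
    """Sample ids inside the West-Eurasian window (lon < 60 E, lat > 35 N)."""
    keep = (meta["lon"] < max_lon) & (meta["lat"] > min_lat)
    return meta.loc[keep, _id_column(meta)].tolist()


# ---------------------------------------------------------------------------
# IBS duplicate detection
# ---------------------------------------------------------------------------

def pairwise_ibs(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state over jointly non-missing sites.

    ``IBS(i, j)`` is the fraction of sites called in both samples where the two
    calls are identical.  Pairs with zero jointly called sites are NaN (IBS
    undefined), never silently 0.  The diagonal is 1.
    """
    if matrix.n_samples < 2:
        raise ValueError("pairwise IBS needs at least 2 samples")
    calls = matrix.calls.astype(np.int16)
    called = (calls != MISSING).astype(np.float64)
    overlap = called @ called.T
    # Count matches over all k states without an n^2 * snps python loop.
    match = np.zeros_like(overlap)
    for state in range(matrix.ploidy + 1):
        ind = (calls == state).astype(np.float64)
        match += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = np.where(overlap > 0, match / np.maximum(overlap, 1), np.nan)
    np.fill_diagonal(ibs, 1.0)
    return pd.DataFrame(ibs, index=matrix.samples, columns=matrix.samples)


@dataclass
class DuplicatePair:
    sample_a: str
    sample_b: str
    ibs: float
    z_score: float
    retained: str


def flag_duplicates(ibs: pd.DataFrame, matrix: GenotypeMatrix, z_threshold: float = 7.0) -> list[DuplicatePair]:
    """Flag duplicate sample pairs from the distribution of per-sample maximum IBS.

    For each sample take its highest off-diagonal IBS; a Z score is computed
    against the mean/SD of these maxima, and samples with Z above the threshold
    are paired with their best match.  The member with fewer missing sites is
    retained (ties break to the lexicographically smaller id).
    """
    values = ibs.to_numpy(dtype=float).copy()
    np.fill_diagonal(values, -np.inf)
    values = np.where(np.isnan(values), -np.inf, values)
    max_ibs = values.max(axis=1)
    best = values.argmax(axis=1)
    sd = max_ibs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("per-sample maximum IBS is constant; Z score undefined")
    z = (max_ibs - max_ibs.mean()) / sd

    n_missing = dict(zip(matrix.samples, matrix.n_missing_per_sample()))
    ids = list(ibs.index)
    seen, out = set(), []
    for i in np.argsort(-z):
        if z[i] <= z_threshold:
            break
        a, b = ids[i], ids[best[i]]
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        if n_missing[a] != n_missing[b]:
            retained = a if n_missing[a] < n_missing[b] else b
        else:
            retained = min(a, b)
        out.append(DuplicatePair(key[0], key[1], float(ibs.loc[a, b]), float(z[i]), retained))
    return out


def dedup_samples(matrix: GenotypeMatrix, z_threshold: float = 7.0) -> tuple[GenotypeMatrix, list[DuplicatePair]]:
    """Drop the discarded member of every flagged duplicate pair."""
    ibs = pairwise_ibs(matrix)
    pairs = flag_duplicates(ibs, matrix, z_threshold=z_threshold)
    drop = {p.sample_a if p.retained == p.sample_b else p.sample_b for p in pairs}
    keep = [s for s in matrix.samples if s not in drop]
    return matrix.subset_samples(keep), pairs
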