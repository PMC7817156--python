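"""Genotype I/O, pseudohaploidization and sample-QC behavior."""

import numpy as np
import pandas as pd
import pytest

from paleoscore.genotype import (
    MISSING,
    EigenstratParseError,
    dedup_samples,
    filter_coverage,
    filter_geography,
    flag_duplicates,
    pairwise_ibs,
    pseudohaploidize,
    read_eigenstrat,
    read_sample_meta,
    read_vcf,
    write_eigenstrat,
    write_sample_meta,
)

from conftest import make_matrix, make_meta


class TestEigenstrat:
    def test_toy_parse_with_missing(self, tmp_path):
        (tmp_path / "t.geno").write_text("09\n11\n00\n")
        (tmp_path / "t.snp").write_text(
            "rs1 1 0.0 100 A G\nrs2 1 0.0 200 C T\nrs3 2 0.0 50 G A\n"
        )
        (tmp_path / "t.ind").write_text("a U Pop\nb U Pop\n")
        gm = read_eigenstrat(tmp_path / "t.geno", tmp_path / "t.snp", tmp_path / "t.ind")
        assert gm.samples == ["a", "b"]
        assert gm.calls[0, 0] == 0 and gm.calls[1, 0] == MISSING
        assert list(gm.calls[:, 1]) == [1, 1]

    def test_row_count_mismatch_names_file_and_line(self, tmp_path):
        (tmp_path / "t.geno").write_text("01\n10\n")
        (tmp_path / "t.snp").write_text(
            "rs1 1 0.0 100 A G\nrs2 1 0.0 200 C T\nrs3 2 0.0 50 G A\n"
        )
        (tmp_path / "t.ind").write_text("a U P\nb U P\n")
        with pytest.raises(EigenstratParseError, match="line 3") as exc:
            read_eigenstrat(tmp_path / "t.geno", tmp_path / "t.snp", tmp_path / "t.ind")
        assert "t.geno" in str(exc.value)

    def test_column_count_mismatch(self, tmp_path):
        (tmp_path / "t.geno").write_text("011\n")
        (tmp_path / "t.snp").write_text("rs1 1 0.0 100 A G\n")
        (tmp_path / "t.ind").write_text("a U P\nb U P\n")
        with pytest.raises(EigenstratParseError, match="line 1"):
            read_eigenstrat(tmp_path / "t.geno", tmp_path / "t.snp", tmp_path / "t.ind")

    def test_round_trip_byte_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, MISSING], size=(6, 30), p=[0.4, 0.4, 0.2])
        gm = make_matrix(calls)
        p1 = [tmp_path / f"a.{e}" for e in ("geno", "snp", "ind")]
        write_eigenstrat(gm, *p1)
        gm2 = read_eigenstrat(*p1)
        p2 = [tmp_path / f"b.{e}" for e in ("geno", "snp", "ind")]
        write_eigenstrat(gm2, *p2)
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()
        assert np.array_equal(gm.calls, gm2.calls)


class TestVCF:
    def test_read_diploid_vcf(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/0\t./.\n"
        )
        gm = read_vcf(vcf)
        assert gm.ploidy == 2
        assert list(gm.calls[:, 0]) == [1, 2]
        assert gm.calls[0, 1] == 0 and gm.calls[1, 1] == MISSING


class TestPseudohaploidize:
    def test_homozygotes_deterministic_and_missing_preserved(self):
        gm = make_matrix([[0, 2, MISSING], [2, 0, 2]], ploidy=2)
        out = pseudohaploidize(gm, seed=1)
        assert list(out.calls[0]) == [0, 1, MISSING]
        assert list(out.calls[1]) == [1, 0, 1]

    def test_heterozygotes_fair_coin(self):
        gm = make_matrix(np.ones((1, 10_000), dtype=int), ploidy=2)
        out = pseudohaploidize(gm, seed=2)
        frac = out.calls.mean()
        se = 0.5 / np.sqrt(10_000)
        assert abs(frac - 0.5) < 3 * se

    def test_reproducible_and_idempotent(self):
        gm = make_matrix(np.tile([0, 1, 2], (4, 5)), ploidy=2)
        a = pseudohaploidize(gm, seed=7)
        b = pseudohaploidize(gm, seed=7)
        assert np.array_equal(a.calls, b.calls)
        assert pseudohaploidize(a, seed=99) is a  # already haploid


class TestCoverageAndGeography:
    def test_coverage_boundary(self):
        meta = make_meta(3)
        meta["coverage"] = [0.05, 0.10, 1.5]
        kept = filter_coverage(meta)
        assert kept == ["ind1", "ind2"]  # 0.05 excluded, 0.10 retained

    def test_all_pass_identity(self):
        meta = make_meta(5)
        meta["coverage"] = 1.0
        assert filter_coverage(meta) == list(meta["sample_id"])

    def test_missing_coverage_errors_with_ids(self):
        meta = make_meta(3)
        meta.loc[1, "coverage"] = np.nan
        with pytest.raises(ValueError, match="ind1"):
            filter_coverage(meta)

    def test_geographic_window(self):
        meta = make_meta(3)
        meta["lon"] = [59.0, 61.0, 10.0]
        meta["lat"] = [50.0, 50.0, 30.0]
        assert filter_geography(meta) == ["ind0"]


class TestMetadataIO:
    def test_round_trip_and_id_normalization(self, tmp_path):
        meta = make_meta(4)
        write_sample_meta(meta, tmp_path / "m.tsv")
        header = (tmp_path / "m.tsv").read_text().splitlines()[0]
        assert header.startswith("id\t")
        back = read_sample_meta(tmp_path / "m.tsv")
        assert list(back["sample_id"]) == list(meta["sample_id"])


class TestIBS:
    def test_extremes_and_direct_count(self):
        m = MISSING
        gm = make_matrix(
            [
                [1, 0, 1, 0, 1, 1],
                [1, 0, 1, 0, 1, 1],   # identical to ind0
                [0, 1, 0, 1, 0, 0],   # opposite of ind0
                [1, 0, 0, 1, m, m],   # 4 shared sites with ind0, 2 match
            ]
        )
        ibs = pairwise_ibs(gm)
        assert ibs.loc["ind0", "ind1"] == 1.0
        assert ibs.loc["ind0", "ind2"] == 0.0
        assert ibs.loc["ind0", "ind3"] == 0.5

    def test_symmetric_unit_diagonal_and_undefined_pair(self):
        m = MISSING
        gm = make_matrix([[1, 0, m, m], [0, 1, m, m], [m, m, 1, 0]])
        ibs = pairwise_ibs(gm)
        arr = ibs.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.all(np.diag(arr) == 1.0)
        assert np.isnan(ibs.loc["ind0", "ind2"])  # zero overlap flagged


def _unrelated(rng, n, L=400):
    freqs = rng.uniform(0.05, 0.95, L)
    return (rng.random((n, L)) < freqs).astype(np.int8)


class TestDuplicateFlagging:
    def test_planted_duplicate_flagged_and_retention(self):
        rng = np.random.default_rng(5)
        calls = _unrelated(rng, 200)
        calls[1] = calls[0]  # exact duplicate pair
        calls[1, :10] = MISSING  # ind1 has more missing data
        gm = make_matrix(calls)
        pairs = flag_duplicates(pairwise_ibs(gm), gm)
        flagged = {(p.sample_a, p.sample_b) for p in pairs}
        assert ("ind0", "ind1") in flagged
        assert next(p for p in pairs if p.sample_a == "ind0").retained == "ind0"

    def test_tie_breaks_to_smaller_id(self):
        rng = np.random.default_rng(6)
        calls = _unrelated(rng, 200)
        calls[11] = calls[2]
        gm = make_matrix(calls)
        pairs = flag_duplicates(pairwise_ibs(gm), gm)
        pair = next(p for p in pairs if p.sample_a == "ind11")
        assert pair.retained == "ind11"  # equal missingness, lexicographic

    def test_no_false_flags_on_unrelated_samples(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            gm = make_matrix(_unrelated(rng, 50, L=300))
            if flag_duplicates(pairwise_ibs(gm), gm):
                hits += 1
        assert hits <= 1  # >= ~95% of replicates clean

    def test_constant_maxima_error(self):
        gm = make_matrix([[1, 0], [1, 0], [1, 0]])
        with pytest.raises(ValueError, match="Z score undefined"):
            flag_duplicates(pairwise_ibs(gm), gm)

    def test_dedup_removes_discarded_member(self):
        rng = np.random.default_rng(8)
        calls = _unrelated(rng, 150)
        calls[3] = calls[2]
        gm = make_matrix(calls)
        cleaned, pairs = dedup_samples(gm)
        assert cleaned.n_samples == 149
        assert len(pairs) == 1
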