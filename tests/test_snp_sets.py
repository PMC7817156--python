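"""Panel construction: orientation, clumping, frequency matching, tagging."""

import numpy as np
import pandas as pd
import pytest

from paleoscore.snp_sets import (
    clump_by_distance,
    clump_greedy_r2,
    load_curated_panel,
    match_frequency,
    orient_to_dark,
    tagging_classification,
)

from conftest import make_matrix


def table(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "pval", "freq"],
    )


class TestOrientation:
    def test_negative_beta_flips_alleles_and_frequency(self):
        t = table([("a", "1", 100, "A", "G", -0.2, 0.01, 1e-9, 0.3)])
        out = orient_to_dark(t)
        row = out.iloc[0]
        assert (row["effect_allele"], row["other_allele"]) == ("G", "A")
        assert row["beta"] == pytest.approx(0.2)
        assert row["freq"] == pytest.approx(0.7)

    def test_positive_rows_unchanged_and_idempotent(self):
        t = table(
            [("a", "1", 100, "A", "G", 0.5, 0.01, 1e-9, 0.3),
             ("b", "1", 200, "C", "T", -0.1, 0.01, 1e-9, 0.8)]
        )
        once = orient_to_dark(t)
        assert once.iloc[0].equals(t.iloc[0])
        assert orient_to_dark(once).equals(once)

    def test_orientation_preserves_genetic_value_differences(self):
        # flipping alleles adds the same constant to every individual's raw
        # genetic value, so pairwise differences are invariant
        rng = np.random.default_rng(0)
        t = table(
            [(f"s{j}", "1", 100 * j + 100, "A", "G",
              float(b), 0.01, 1e-9, 0.5) for j, b in enumerate(rng.normal(0, 0.3, 8))]
        )
        oriented = orient_to_dark(t)
        d_raw = rng.integers(0, 2, size=(5, 8)).astype(float)
        flipped = (t["beta"] < 0).to_numpy()
        d_or = np.where(flipped[None, :], 1 - d_raw, d_raw)
        g_raw = d_raw @ t["beta"].to_numpy()
        g_or = d_or @ oriented["beta"].to_numpy()
        diff_raw = g_raw[:, None] - g_raw[None, :]
        diff_or = g_or[:, None] - g_or[None, :]
        assert np.allclose(diff_raw, diff_or, atol=1e-12)


class TestDistanceClump:
    def test_within_100kb_keeps_best_p(self):
        t = table(
            [("a", "1", 1_000_000, "A", "G", 0.1, 0.01, 1e-30, 0.5),
             ("b", "1", 1_050_000, "A", "G", 0.1, 0.01, 1e-9, 0.5)]
        )
        assert list(clump_by_distance(t)["snp_id"]) == ["a"]

    def test_beyond_window_and_cross_chromosome_kept(self):
        t = table(
            [("a", "1", 1_000_000, "A", "G", 0.1, 0.01, 1e-30, 0.5),
             ("b", "1", 1_150_000, "A", "G", 0.1, 0.01, 1e-9, 0.5),
             ("c", "2", 1_000_001, "A", "G", 0.1, 0.01, 1e-9, 0.5)]
        )
        assert set(clump_by_distance(t)["snp_id"]) == {"a", "b", "c"}

    def test_no_retained_pair_violates_rule(self):
        rng = np.random.default_rng(1)
        t = table(
            [(f"s{j}", str(rng.integers(1, 3)), int(rng.integers(1, 3e6)),
              "A", "G", 0.1, 0.01, float(rng.uniform(1e-30, 1e-8)), 0.5)
             for j in range(60)]
        )
        out = clump_by_distance(t)
        assert set(out["snp_id"]) <= set(t["snp_id"])
        for _, a in out.iterrows():
            for _, b in out.iterrows():
                if a["snp_id"] != b["snp_id"] and a["chrom"] == b["chrom"]:
                    assert abs(a["pos"] - b["pos"]) >= 100_000


def _ld_block_reference(rng, n_blocks=5, snps_per_block=4, n_samples=200, spacing=20_000):
    """Reference panel of LD blocks: near-perfect LD within, none between."""
    cols, ids, pos = [], [], []
    for b in range(n_blocks):
        anchor = (rng.random(n_samples) < 0.5).astype(np.int8)
        for j in range(snps_per_block):
            col = anchor.copy()
            flip = rng.random(n_samples) < 0.02  # r2 ~ 0.92
            col[flip] = 1 - col[flip]
            cols.append(col)
            ids.append(f"b{b}_s{j}")
            pos.append(b * 1_000_000 + j * spacing + 1)
    calls = np.stack(cols, axis=1)
    gm = make_matrix(calls)
    for rec, new_id, p in zip(gm.snps, ids, pos):
        object.__setattr__(rec, "id", new_id)
        object.__setattr__(rec, "pos", p)
    return gm, ids, pos


class TestGreedyR2Clump:
    def test_pairwise_examples(self):
        rng = np.random.default_rng(2)
        anchor = (rng.random(300) < 0.5).astype(np.int8)
        noisy = anchor.copy()
        flip = rng.random(300) < 0.02
        noisy[flip] = 1 - noisy[flip]
        gm = make_matrix(np.stack([anchor, noisy, anchor], axis=1))
        # s0 and s1: 10 kb apart in high LD -> only better p kept
        t = table(
            [("s0", "1", 1000, "A", "G", 0.1, 0.01, 1e-20, 0.5),
             ("s1", "1", 11_000, "A", "G", 0.1, 0.01, 1e-10, 0.5)]
        )
        assert list(clump_greedy_r2(t, gm)["snp_id"]) == ["s0"]
        # same LD but 500 kb apart -> both kept
        t2 = table(
            [("s0", "1", 1000, "A", "G", 0.1, 0.01, 1e-20, 0.5),
             ("s2", "1", 501_000, "A", "G", 0.1, 0.01, 1e-10, 0.5)]
        )
        gm2 = make_matrix(np.stack([anchor, noisy], axis=1))
        object.__setattr__(gm2.snps[1], "id", "s2")
        object.__setattr__(gm2.snps[1], "pos", 501_000)
        assert set(clump_greedy_r2(t2, gm2)["snp_id"]) == {"s0", "s2"}

    def test_five_blocks_give_five_index_snps(self):
        rng = np.random.default_rng(3)
        gm, ids, pos = _ld_block_reference(rng)
        t = table(
            [(i, "1", p, "A", "G", 0.1, 0.01, float(rng.uniform(1e-20, 1e-9)), 0.5)
             for i, p in zip(ids, pos)]
        )
        out = clump_greedy_r2(t, gm)
        assert len(out) == 5
        assert len({i.split("_")[0] for i in out["snp_id"]}) == 5

    def test_subsignificant_snps_dropped(self):
        rng = np.random.default_rng(4)
        gm, ids, pos = _ld_block_reference(rng, n_blocks=2)
        t = table(
            [(ids[0], "1", pos[0], "A", "G", 0.1, 0.01, 1e-9, 0.5),
             (ids[4], "1", pos[4], "A", "G", 0.1, 0.01, 1e-4, 0.5)]
        )
        assert list(clump_greedy_r2(t, gm)["snp_id"]) == [ids[0]]


class TestMatchFrequency:
    def test_candidates_within_tolerance(self):
        rng = np.random.default_rng(0)
        pool = rng.uniform(0, 1, 5000)
        targets = np.array([0.30, 0.62])
        sets = match_frequency(targets, pool, n_sets=50, seed=1)
        assert sets.shape == (50, 2)
        for t_idx, t in enumerate(targets):
            assert np.all(np.abs(pool[sets[:, t_idx]] - t) <= 0.01 + 1e-12)

    def test_reproducible_and_distinct_within_set(self):
        pool = np.linspace(0, 1, 2000)
        targets = np.full(5, 0.5)
        a = match_frequency(targets, pool, n_sets=20, seed=9)
        b = match_frequency(targets, pool, n_sets=20, seed=9)
        assert np.array_equal(a, b)
        for row in a:
            assert len(set(row)) == len(row)  # without replacement within set

    def test_empty_bin_errors_with_frequency(self):
        pool = np.array([0.9, 0.95])
        with pytest.raises(ValueError, match="0.3000"):
            match_frequency([0.30], pool, n_sets=1, seed=0)

    def test_exclusion_mask_respected(self):
        pool = np.array([0.30, 0.301, 0.299])
        sets = match_frequency([0.30], pool, n_sets=30, seed=2, exclude=[0])
        assert 0 not in set(sets.ravel())


class TestTagging:
    def test_classes(self):
        rng = np.random.default_rng(5)
        anchor = (rng.random(400) < 0.5).astype(np.int8)
        perfect = anchor.copy()
        moderate = anchor.copy()
        flip = rng.random(400) < 0.08  # realized r2 ~ 0.65
        moderate[flip] = 1 - moderate[flip]
        indep = (rng.random(400) < 0.5).astype(np.int8)
        gm = make_matrix(np.stack([anchor, perfect, moderate, indep], axis=1))
        a = table(
            [("s0", "1", 1000, "A", "G", 0.1, 0.01, 1e-9, 0.5),     # shared
             ("s1", "1", 11_000, "A", "G", 0.1, 0.01, 1e-9, 0.5),   # perfect LD
             ("s2", "1", 21_000, "A", "G", 0.1, 0.01, 1e-9, 0.5),   # moderate LD
             ("s3", "1", 31_000, "A", "G", 0.1, 0.01, 1e-9, 0.5)]   # independent
        )
        b = table([("s0", "1", 1000, "A", "G", 0.1, 0.01, 1e-9, 0.5)])
        out = tagging_classification(a, b, gm)
        assert list(out["tag_class"]) == ["shared", "r2_ge_0.8", "r2_ge_0.5", "untagged"]


def test_curated_panel_fixture_loads():
    panel = load_curated_panel()
    assert len(panel) == 18
    assert {"snp_id", "chrom", "pos", "effect_allele", "other_allele"} <= set(panel.columns)
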