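"""Score-time regression, empirical null machinery, stratification,
leave-top-k, per-SNP models and LRTs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import paleoscore as ps
from paleoscore.genotype import MISSING
from paleoscore.glm import fit_binomial_logit
from paleoscore.time_series import (
    EmpiricalTest,
    _one_sided_p,
    assign_ancestry_group,
    build_design,
    effect_vs_change_regression,
    empirical_null_pvalue,
    fit_score_glm,
    leave_top_k,
    lrt,
    per_snp_scan,
    snp_logistic,
    stratified_score_test,
)

from conftest import make_matrix, make_meta


class TestEmpiricalMachinery:
    def test_one_sided_and_two_sided_counting(self):
        null = np.array([-1.0, 0.0, 1.0, 2.0])
        assert _one_sided_p(1.5, null, "decrease") == pytest.approx(2 / 5)
        assert _one_sided_p(1.5, null, "increase") == pytest.approx(4 / 5)
        assert _one_sided_p(1.5, null, "two_sided") == pytest.approx(2 / 5)

    def test_report_bound_when_beyond_all_nulls(self):
        t = EmpiricalTest(3.0, np.zeros(10_000), 1 / 10_001, 10_000)
        assert t.p_report == "P < 0.0001"
        t2 = EmpiricalTest(0.0, np.zeros(100), 0.5, 100)
        assert t2.p_report.startswith("P = ")

    def test_same_seed_identical_p(self, small_neutral, small_neutral_pcs):
        d = small_neutral
        kw = dict(b=150, seed=42)
        a = empirical_null_pvalue(d.matrix, d.effect_table, d.meta,
                                  small_neutral_pcs, d.pool, **kw)
        b = empirical_null_pvalue(d.matrix, d.effect_table, d.meta,
                                  small_neutral_pcs, d.pool, **kw)
        assert a.p_empirical == b.p_empirical
        assert np.array_equal(a.null_betas, b.null_betas)

    def test_pool_must_exclude_trait_snps(self, small_neutral, small_neutral_pcs):
        d = small_neutral
        bad_pool = pd.concat(
            [d.pool, d.effect_table[["snp_id", "freq"]].head(1)], ignore_index=True
        )
        with pytest.raises(ValueError, match="exclude trait"):
            empirical_null_pvalue(d.matrix, d.effect_table, d.meta,
                                  small_neutral_pcs, bad_pool, b=100, seed=0)

    def test_date_unit_rescaling_preserves_p(self, small_neutral, small_neutral_pcs):
        d = small_neutral
        a = empirical_null_pvalue(d.matrix, d.effect_table, d.meta,
                                  small_neutral_pcs, d.pool, b=150, seed=5)
        meta_ka = d.meta.assign(date_bp=d.meta["date_bp"] / 1000.0)
        b = empirical_null_pvalue(d.matrix, d.effect_table, meta_ka,
                                  small_neutral_pcs, d.pool, b=150, seed=5)
        assert b.p_empirical == a.p_empirical
        assert b.observed_beta_date == pytest.approx(1000 * a.observed_beta_date, rel=1e-5)


class TestParameterRecoverySmall:
    def test_simulated_slope_recovered(self):
        rng = np.random.default_rng(0)
        est = []
        for rep in range(20):
            n, m = 400, 80
            meta = make_meta(n, dates=rng.uniform(0, 15000, n), seed=1000 + rep)
            X = np.column_stack(
                [np.ones(n), meta["date_bp"], meta["lat"], meta["lon"]]
            )
            beta = np.array([0.6, -5e-5, -0.002, 0.001])
            s = rng.binomial(m, expit(X @ beta))
            records = pd.DataFrame(
                {"sample_id": meta["sample_id"], "m": m, "score": s / m, "weighted": False}
            )
            fit = fit_score_glm(records, meta, pcs=None)
            est.append(fit.coef("date_bp"))
        assert np.median(est) == pytest.approx(-5e-5, rel=0.15)


class TestAncestryGroups:
    def q(self, hg, ef, st):
        return pd.DataFrame(
            {"sample_id": ["x"], "hunter_gatherer": [hg],
             "early_farmer": [ef], "steppe": [st]}
        )

    def meta(self, date):
        return pd.DataFrame({"sample_id": ["x"], "date_bp": [date]})

    def test_hunter_gatherer_cutoff(self):
        lab = assign_ancestry_group(self.q(0.7, 0.2, 0.1), self.meta(9000))
        assert lab.loc["x"] == "hunter_gatherer"

    def test_steppe_requires_recent_date(self):
        assert assign_ancestry_group(self.q(0.3, 0.35, 0.35), self.meta(4000)).loc["x"] == "steppe"
        assert assign_ancestry_group(self.q(0.3, 0.35, 0.35), self.meta(6000)).loc["x"] == "unassigned"

    def test_steppe_precedence_over_early_farmer(self):
        lab = assign_ancestry_group(self.q(0.04, 0.65, 0.31), self.meta(4500))
        assert lab.loc["x"] == "steppe"

    def test_early_farmer(self):
        assert assign_ancestry_group(self.q(0.2, 0.65, 0.15), self.meta(6000)).loc["x"] == "early_farmer"

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            assign_ancestry_group(self.q(0.5, 0.1, 0.1), self.meta(1000))


class TestLRT:
    def fit(self, X, y, terms):
        return fit_binomial_logit(X, y, np.ones_like(y), terms=terms)

    def test_identical_models_p_one(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = (rng.random(60) < 0.4).astype(float)
        f = self.fit(X, y, ["intercept", "a"])
        assert lrt(f, f, df=1) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)

    def test_statistic_nonnegative_and_failure_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        X = np.column_stack([np.ones(80), x])
        y = (rng.random(80) < expit(0.5 * x)).astype(float)
        full = self.fit(X, y, ["intercept", "a"])
        nested = self.fit(X[:, :1], y, ["intercept"])
        assert 2 * (full.llf - nested.llf) >= 0
        assert 0 <= lrt(full, nested) <= 1
        from dataclasses import replace

        broken = replace(full, llf=nested.llf - 1.0)  # impossible likelihood
        with pytest.raises(ValueError, match="fit failure"):
            lrt(broken, nested)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = (rng.random(40) < 0.5).astype(float)
        a = self.fit(X, y, ["intercept", "a"])
        b = self.fit(X, y, ["intercept", "b"])
        with pytest.raises(ValueError, match="not nested"):
            lrt(a, b)


class TestPerSNP:
    def test_monomorphic_skipped(self):
        calls = np.ones((40, 1), dtype=np.int8)
        gm = make_matrix(calls)
        meta = make_meta(40)
        assert snp_logistic(gm, "s0", meta) is None

    def test_undersized_skipped(self):
        calls = np.array([[0], [1]] * 5, dtype=np.int8)
        gm = make_matrix(calls)
        meta = make_meta(10)
        assert snp_logistic(gm, "s0", meta, min_samples=30) is None

    def test_frequency_rise_sign_recovered(self):
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(20):
            n = 500
            dates = rng.uniform(0, 10_000, n)
            p = expit(np.log(0.25 / 0.75) + (10_000 - dates) / 10_000 * 2 * np.log(3))
            calls = (rng.random(n) < p).astype(np.int8)[:, None]
            gm = make_matrix(calls)
            gm.samples[:] = [f"ind{i}" for i in range(n)]
            meta = make_meta(n, dates=dates)
            fit = snp_logistic(gm, "s0", meta)
            if fit is not None and fit.coef("date_bp") < 0:
                hits += 1  # allele rises toward the present -> negative BP slope
        assert hits >= 19

    def test_scan_output_structure(self, small_neutral, small_neutral_pcs):
        d = small_neutral
        scan = per_snp_scan(d.matrix, d.trait_snp_ids[:10], d.meta, small_neutral_pcs)
        ok = scan[scan["skip"] == ""]
        assert {"beta_date", "p_date", "p_ancestry"} <= set(scan.columns)
        assert ok["p_date"].between(0, 1).all()
        assert ok["p_ancestry"].between(0, 1).all()


class TestLeaveTopK:
    def test_full_panel_attenuation_zero(self, small_neutral, small_neutral_pcs):
        d = small_neutral
        out = leave_top_k(d.matrix, d.effect_table, [0, 2], d.meta, small_neutral_pcs)
        assert out.loc[out["k"] == 0, "attenuation_pct"].iloc[0] == 0.0

    def test_k_exceeding_panel_errors(self, small_neutral, small_neutral_pcs):
        d = small_neutral
        with pytest.raises(ValueError, match="panel size"):
            leave_top_k(d.matrix, d.effect_table, [len(d.effect_table)], d.meta,
                        small_neutral_pcs)

    def test_single_selected_top_snp_attenuates(self):
        cfg = ps.make_preset(
            "sweep-top", n_snps_null=1500, n_snps_trait=30,
            n_individuals=250, selected_top_k=1, selection_s=0.03,
        )
        atten = []
        for seed in range(6):
            d = ps.simulate_dataset(cfg, seed=100 + seed)
            out = leave_top_k(d.matrix, d.effect_table, [1], d.meta, pcs=None)
            atten.append(out.loc[out["k"] == 1, "attenuation_pct"].iloc[0])
        assert np.mean(atten) >= 60.0


class TestStratified:
    def test_identical_groups_zero_interaction(self):
        # two copies of the same samples labelled as different groups: the
        # group x date interaction must vanish
        rng = np.random.default_rng(5)
        n, m = 150, 40
        meta = make_meta(n)
        X = np.column_stack([np.ones(n), meta["date_bp"]])
        s = rng.binomial(m, expit(-0.4 + 4e-5 * meta["date_bp"]))
        X2 = np.vstack([X, X])
        dummy = np.repeat([0.0, 1.0], n)
        X2 = np.column_stack([X2, dummy, dummy * X2[:, 1]])
        fit = fit_binomial_logit(
            X2, np.tile(s, 2).astype(float), np.full(2 * n, float(m)),
            terms=["intercept", "date_bp", "group", "date_x_group"],
        )
        assert fit.coef("date_x_group") == pytest.approx(0.0, abs=1e-10)
        assert fit.coef("group") == pytest.approx(0.0, abs=1e-8)

    def test_structure_and_skipping(self, small_neutral, small_neutral_pcs):
        d = small_neutral
        groups = assign_ancestry_group(d.q, d.meta)
        res = stratified_score_test(
            d.matrix, d.effect_table, d.meta, small_neutral_pcs, groups, d.pool,
            b=120, seed=1, min_group_size=20,
        )
        for g, test in res["per_group"].items():
            assert 0 < test.p_empirical <= 1
        assert set(res["skipped"]) | set(res["per_group"]) >= {"hunter_gatherer"}


class TestEffectVsChange:
    def scan_from(self, beta_dates):
        return pd.DataFrame(
            {"snp_id": [f"t{j}" for j in range(len(beta_dates))],
             "skip": "", "beta_date": beta_dates}
        )

    def effects(self, betas):
        return pd.DataFrame({"snp_id": [f"t{j}" for j in range(len(betas))],
                             "beta": betas})

    def test_proportional_gives_r2_one(self):
        b = np.linspace(0.1, 1.0, 12)
        out = effect_vs_change_regression(self.effects(b), self.scan_from(3 * b))
        assert out["adj_r2"] == pytest.approx(1.0, abs=1e-10)
        assert out["slope"] == pytest.approx(3.0, abs=1e-10)

    def test_independent_gives_near_zero_r2(self):
        rng = np.random.default_rng(6)
        b = rng.uniform(0.1, 1.0, 200)
        out = effect_vs_change_regression(
            self.effects(b), self.scan_from(rng.normal(0, 1e-4, 200))
        )
        assert abs(out["adj_r2"]) < 0.05

    def test_two_points_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            effect_vs_change_regression(self.effects([0.1, 0.2]),
                                        self.scan_from([1e-5, 2e-5]))
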