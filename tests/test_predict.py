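import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit as sp_logit

import gwasrep as g
from conftest import brute_force_auc


def _dataset_frame(n=200, frac_replicated=0.6, seed=0):
    rng = np.random.default_rng(seed)
    repl = (rng.random(n) < frac_replicated).astype(int)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(n)],
            "trait_name": "t",
            "replicated": repl,
            "or_discovery": np.exp(rng.normal(0.2, 0.05, n)),
            "p_category": rng.choice(g.P_BIN_LABELS, n),
            "neglog10_p": rng.uniform(8, 30, n),
            "trait_type": rng.choice(["binary", "quantitative"], n),
            "maf": rng.uniform(0.05, 0.5, n),
            "info": rng.uniform(0.7, 1.0, n),
            "sample_size_ratio": rng.uniform(0.5, 5.0, n),
        }
    )


class TestMakeDataset:
    def test_p_category_assignment(self):
        assert g.p_value_category(np.array([2e-10]))[0] == "5e-10 to 5e-11"
        assert g.p_value_category(np.array([2e-11]))[0] == "< 5e-11"

    def test_missing_info_rows_excluded_and_counted(self, sim_harmonized):
        snvs = sim_harmonized["harm"].table.copy()
        calls = sim_harmonized["calls"]
        eligible_ids = calls.loc[calls["significant_discovery"], "variant_id"]
        victim = eligible_ids.iloc[0]
        snvs.loc[snvs["variant_id"] == victim, "info_replication"] = np.nan
        ds = g.make_dataset(snvs, calls)
        assert ds.drops == {"missing_info": 1}
        assert victim not in set(ds.frame["variant_id"])
        assert ds.n_input == len(ds.frame) + 1

    def test_outcome_mean_matches_replicated_fraction(self, sim_harmonized):
        snvs, calls = sim_harmonized["harm"].table, sim_harmonized["calls"]
        ds = g.make_dataset(snvs, calls)
        k = calls["replicated"].sum()
        n = calls["significant_discovery"].sum()
        assert ds.frame["replicated"].mean() == pytest.approx(k / n)

    def test_too_few_rows_errors(self, sim_harmonized):
        snvs, calls = sim_harmonized["harm"].table, sim_harmonized["calls"]
        with pytest.raises(ValueError, match="model not fit"):
            g.make_dataset(snvs, calls, min_rows=10**6)


class TestSplit:
    def test_odd_count_splits_within_one(self):
        frame = _dataset_frame(101)
        train, test = g.split_train_test(frame, seed=1)
        assert {len(train), len(test)} == {50, 51}
        assert len(set(train["variant_id"]) & set(test["variant_id"])) == 0

    def test_same_seed_reproduces_split(self):
        frame = _dataset_frame(300)
        t1 = g.split_train_test(frame, seed=9)
        t2 = g.split_train_test(frame, seed=9)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])

    def test_different_seeds_differ(self):
        frame = _dataset_frame(1000)
        a, _ = g.split_train_test(frame, seed=1)
        b, _ = g.split_train_test(frame, seed=2)
        assert not a.equals(b)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        frame = _dataset_frame(400, frac_replicated=0.7, seed=2)
        fit = g.fit_logistic(frame, formula="replicated ~ 1")
        pbar = frame["replicated"].mean()
        est = fit.coefficients.set_index("term").loc["Intercept", "estimate"]
        assert est == pytest.approx(sp_logit(pbar), rel=1e-8)
        assert fit.mcfadden_r2 == 0.0

    def test_recovers_single_strong_coefficient(self):
        rng = np.random.default_rng(13)
        n = 5000
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        frame = pd.DataFrame({"replicated": y, "x": x})
        fit = g.fit_logistic(frame, formula="replicated ~ x")
        row = fit.coefficients.set_index("term").loc["x"]
        assert abs(row["estimate"] - 2.0) < 3 * row["se"]

    def test_single_class_train_errors(self):
        frame = _dataset_frame(100, frac_replicated=1.0)
        frame["replicated"] = 1
        with pytest.raises(ValueError, match="single outcome class"):
            g.fit_logistic(frame)

    def test_perfect_separation_is_flagged_and_penalized(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 200)
        frame = pd.DataFrame({"replicated": (x > 0).astype(int), "x": x})
        fit = g.fit_logistic(frame, formula="replicated ~ x")
        assert fit.separation_flag and fit.penalized
        assert np.all(np.isfinite(fit.predict(frame)))

    def test_mcfadden_increases_weakly_for_nested_models(self):
        rng = np.random.default_rng(21)
        n = 3000
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        frame = pd.DataFrame({"replicated": y, "x": x, "junk": rng.normal(0, 1, n)})
        r2_null = g.fit_logistic(frame, formula="replicated ~ 1").mcfadden_r2
        r2_x = g.fit_logistic(frame, formula="replicated ~ x").mcfadden_r2
        r2_xj = g.fit_logistic(frame, formula="replicated ~ x + junk").mcfadden_r2
        assert r2_null == 0.0
        assert r2_x > r2_null
        assert r2_xj >= r2_x - 1e-12


class TestEvaluate:
    def _fit_and_eval(self, train, test, rule="youden"):
        fit = g.fit_logistic(train)
        return g.evaluate(fit, test, rule)

    def test_perfectly_separating_score_gives_auc_one(self):
        y = np.array([0] * 50 + [1] * 50)
        s = np.concatenate([np.linspace(0.0, 0.4, 50), np.linspace(0.6, 1.0, 50)])
        auc, lo, hi = g.delong_auc_ci(y, s)
        assert auc == 1.0 and hi == 1.0

    def test_random_score_auc_near_half(self):
        rng = np.random.default_rng(31)
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        auc, lo, hi = g.delong_auc_ci(y, s)
        assert lo < 0.5 < hi

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_delong_point_estimate_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 2)  # rounding forces ties
        auc, _, _ = g.delong_auc_ci(y, s)
        assert auc == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 500)
        y[:2] = [0, 1]
        s = rng.random(500)
        a1, _, _ = g.delong_auc_ci(y, s)
        a2, _, _ = g.delong_auc_ci(y, np.exp(5 * s) + 3)
        assert a1 == pytest.approx(a2, abs=1e-14)

    def test_metrics_on_simulated_pipeline_data(self, sim_harmonized):
        ds = g.make_dataset(sim_harmonized["harm"].table, sim_harmonized["calls"])
        train, test = g.split_train_test(ds, seed=3)
        # single simulated trait: trait_type and ratio terms drop automatically
        fit = g.fit_logistic(train)
        metrics, roc = g.evaluate(fit, test)
        assert 0.0 <= metrics.auc <= 1.0
        assert metrics.sens_ci_low <= metrics.sensitivity <= metrics.sens_ci_high
        assert metrics.spec_ci_low <= metrics.specificity <= metrics.spec_ci_high
        assert list(roc.columns) == ["threshold", "fpr", "tpr"]

    def test_half_threshold_rule(self):
        frame = _dataset_frame(600, seed=8)
        frame["or_discovery"] = np.where(frame["replicated"] == 1, 1.4, 1.1) * np.exp(
            np.random.default_rng(0).normal(0, 0.05, 600)
        )
        train, test = g.split_train_test(frame, seed=0)
        metrics, _ = self._fit_and_eval(train, test, rule="half")
        assert metrics.threshold == 0.5 and metrics.threshold_rule == "half"

    def test_single_class_test_set_errors(self):
        frame = _dataset_frame(200, seed=10)
        train, test = g.split_train_test(frame, seed=0)
        test = test.assign(replicated=1)
        fit = g.fit_logistic(train)
        with pytest.raises(ValueError, match="single outcome class"):
            g.evaluate(fit, test)
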