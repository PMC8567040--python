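import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import mann_whitney_auc
from sloquant.score import (choose_cutoff, composite_score, cutoff_table,
                            fit_linear, roc, zscore)


class TestZscore:
    def test_1_2_3_maps_to_unit_steps(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_constant_stratum_is_error(self):
        with pytest.raises(ValueError, match="constant stratum"):
            zscore([5.0, 5.0, 5.0])

    def test_single_value_stratum_is_error(self):
        with pytest.raises(ValueError, match="need >= 2"):
            zscore([1.0, 2.0, 3.0], strata=["a", "a", "b"])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=30, unique=True))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_output_mean_zero_sd_one(self, values):
        z = zscore(values)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.std(z, ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_stratified_standardization_per_stratum(self, rng):
        x = rng.normal(50, 9, 40)
        strata = np.repeat(["w0", "w6"], 20)
        x[strata == "w6"] += 100
        z = zscore(x, strata)
        for s in ("w0", "w6"):
            assert np.mean(z[strata == s]) == pytest.approx(0.0, abs=1e-9)
            assert np.std(z[strata == s], ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestComposite:
    def _table(self, rng, n=24):
        return pd.DataFrame({
            "week": np.repeat([0, 6], n // 2),
            "cc": rng.normal(40, 8, n),
            "sua": rng.normal(900, 150, n),
            "group": ["EAE", "sham"] * (n // 2),
        })

    def test_composite_is_mean_of_z_components(self, rng):
        out = composite_score(self._table(rng), components=("cc", "sua"))
        np.testing.assert_allclose(out["composite"],
                                   (out["z_cc"] + out["z_sua"]) / 2)

    def test_single_component_composite_equals_its_zscore(self, rng):
        out = composite_score(self._table(rng), components=("cc",))
        np.testing.assert_allclose(out["composite"], out["z_cc"])

    def test_identical_components_collapse_to_one(self, rng):
        tab = self._table(rng)
        tab["cc2"] = tab["cc"]
        out = composite_score(tab, components=("cc", "cc2"))
        np.testing.assert_allclose(out["composite"], out["z_cc"])

    def test_missing_component_is_error(self, rng):
        with pytest.raises(KeyError, match="mvi"):
            composite_score(self._table(rng), components=("cc", "mvi"))

    def test_strata_column_respected(self, rng):
        out = composite_score(self._table(rng), strata="week")
        for w in (0, 6):
            sub = out[out["week"] == w]
            assert sub["z_cc"].mean() == pytest.approx(0.0, abs=1e-9)
            assert sub["z_cc"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestRoc:
    def test_worked_example_auc_three_quarters(self):
        r = roc([3, 1, 2, 0], ["pos", "pos", "neg", "neg"], positive="pos")
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = roc([10, 9, 1, 0], [1, 1, 0, 0], positive=1)
        assert r.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        r = roc([5, 5, 5, 5], [1, 1, 0, 0], positive=1)
        assert r.auc == pytest.approx(0.5)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2], [1, 1], positive=1)

    def test_sensitivity_monotone_in_threshold(self, rng):
        r = roc(rng.normal(size=30), rng.integers(0, 2, 30), positive=1)
        assert (np.diff(r.sensitivity) <= 1e-12).all()
        assert (np.diff(r.specificity) >= -1e-12).all()

    def test_matches_mann_whitney_oracle_on_random_sets(self, rng):
        for _ in range(60):
            n_pos = int(rng.integers(2, 9))
            n_neg = int(rng.integers(2, 9))
            pos = rng.integers(0, 6, n_pos).astype(float)
            neg = rng.integers(0, 6, n_neg).astype(float)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * n_pos + [0] * n_neg)
            assert roc(scores, labels, 1).auc == pytest.approx(
                mann_whitney_auc(pos, neg), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert roc(scores, labels, 1).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_reversed_scores_complement(self, rng):
        scores = rng.normal(size=30)   # ties almost surely absent
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = roc(scores, labels, 1).auc
        b = roc(-scores, labels, 1).auc
        assert a + b == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = roc(scores, labels, 1).auc
        b = roc(np.exp(scores), labels, 1).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestChooseCutoff:
    def test_balanced_follows_stated_rule_on_worked_input(self):
        # candidates for {3,1} vs {2,0}: the midpoint 1.5 achieves
        # sens = spec = 0.5, the unique minimizer of |sens - spec|
        r = roc([3, 1, 2, 0], [1, 1, 0, 0], positive=1)
        cutoff, sens, spec = choose_cutoff(r, "balanced")
        assert (cutoff, sens, spec) == (1.5, 0.5, 0.5)

    def test_balanced_is_optimal_among_all_candidates(self, rng):
        for _ in range(20):
            scores = rng.normal(size=16)
            labels = rng.integers(0, 2, 16)
            labels[:2] = [0, 1]
            r = roc(scores, labels, 1)
            _, sens, spec = choose_cutoff(r, "balanced")
            tab = cutoff_table(r)
            best = np.abs(tab["sensitivity"] - tab["specificity"]).min()
            assert abs(sens - spec) == pytest.approx(best, abs=1e-12)

    def test_perfect_separation_any_strategy(self):
        r = roc([9, 8, 2, 1], [1, 1, 0, 0], positive=1)
        for strategy, floor in [("balanced", None), ("youden", None),
                                ("sens_floor", 1.0), ("spec_floor", 1.0)]:
            _, sens, spec = choose_cutoff(r, strategy, floor=floor)
            assert sens == 1.0 and spec == 1.0

    def test_youden_maximizes_sens_plus_spec(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        r = roc(scores, labels, 1)
        _, sens, spec = choose_cutoff(r, "youden")
        tab = cutoff_table(r)
        assert sens + spec == pytest.approx(
            (tab["sensitivity"] + tab["specificity"]).max(), abs=1e-12)

    def test_infeasible_floor_is_error(self):
        r = roc([3, 1, 2, 0], [1, 1, 0, 0], positive=1)
        with pytest.raises(ValueError, match="infeasible"):
            choose_cutoff(r, "sens_floor", floor=1.1)

    def test_cutoff_table_has_all_candidates(self):
        r = roc([3, 1, 2, 0], [1, 1, 0, 0], positive=1)
        tab = cutoff_table(r)
        assert len(tab) == 5   # below-min, 3 midpoints, above-max
        assert tab["sensitivity"].iloc[0] == 1.0
        assert tab["specificity"].iloc[-1] == 1.0


class TestFitLinear:
    def test_exact_line(self):
        fit = fit_linear([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_closed_form_worked_example(self):
        # x={1,2,3}, y={1,2,2}: Pearson r^2 = 1 / (2 * 2/3) = 0.75
        fit = fit_linear([1, 2, 3], [1, 2, 2])
        assert fit.r_squared == pytest.approx(0.75)

    def test_orthogonal_fixture_has_zero_r2(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # cov(x, y) = 0 exactly
        assert fit_linear(x, y).r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_on_random_data(self, rng):
        for _ in range(10):
            x = rng.normal(size=12)
            y = 3 * x + rng.normal(size=12)
            fit = fit_linear(x, y)
            A = np.vstack([x, np.ones_like(x)]).T
            slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
            assert fit.slope == pytest.approx(slope)
            assert fit.intercept == pytest.approx(intercept)

    def test_constant_x_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([2, 2, 2], [1, 2, 3])

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_linear([1, 2], [1, 2])
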