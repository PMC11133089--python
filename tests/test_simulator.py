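import numpy as np
import pytest
from scipy.special import ndtr

from ordmi import (
    FactorParams,
    GroupMeasurementParams,
    OrdinalDataset,
    dichotomize,
    load_parameter_set,
    make_condition,
    simulate_dataset,
)
from ordmi.moments import category_probabilities, distribution_skewness
from ordmi.params import tabulated_skewness


class TestParameterSets:
    def test_negatively_skewed_binary(self):
        ps = load_parameter_set("negatively_skewed", 2)
        assert ps.n_items == 10
        assert np.all(ps.loadings == 0.6)
        assert np.all(ps.unique_variances == 0.64)
        assert np.all(ps.thresholds == -0.59)
        assert np.all(ps.intercepts == 0)

    def test_negatively_skewed_five_categories(self):
        ps = load_parameter_set("negatively_skewed", 5)
        np.testing.assert_allclose(
            ps.thresholds, np.tile([-1.55, -1.08, -0.55, 0.15], (10, 1))
        )

    def test_bacs_binary_item1(self):
        ps = load_parameter_set("BACS", 2)
        assert ps.n_items == 7
        assert ps.loadings[0] == 2.68
        assert ps.unique_variances[0] == 1.0
        # thresholds are tabulated on the standardized scale; the raw scale
        # rescales by sqrt(lambda^2 + theta)
        assert ps.thresholds_std[0, 0] == -2.92
        assert ps.thresholds[0, 0] == pytest.approx(-2.92 * np.sqrt(2.68**2 + 1))

    def test_unknown_set_lists_valid_names(self):
        with pytest.raises(ValueError, match="negatively_skewed"):
            load_parameter_set("nope", 2)
        with pytest.raises(ValueError, match="valid"):
            load_parameter_set("BACS", 7)


class TestMakeCondition:
    def test_focal_theta_pattern(self):
        cond = make_condition("negatively_skewed", 500, 2, 3, 1.5**2, 0.0)
        np.testing.assert_allclose(cond.focal.unique_variances[-3:], 1.44)
        np.testing.assert_allclose(cond.focal.unique_variances[:-3], 0.64)
        assert list(cond.noninvariant_items) == [7, 8, 9]

    def test_invariant_when_pni_zero(self):
        cond = make_condition("negatively_skewed", 100, 5, 0, 1.0, 0.2)
        np.testing.assert_array_equal(
            cond.focal.unique_variances, cond.reference.unique_variances
        )
        np.testing.assert_array_equal(cond.focal.thresholds, cond.reference.thresholds)

    def test_bacs_small_noninvariance(self):
        cond = make_condition("BACS", 500, 5, 3, 1.25**2, 0.5)
        np.testing.assert_allclose(cond.focal.unique_variances[-3:], 1.5625)

    def test_too_many_noninvariant_items(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_condition("BACS", 500, 5, 8, 2.25, 0.0)


class TestSimulateDataset:
    def test_deterministic_given_seed(self):
        cond = make_condition("negatively_skewed", 200, 5, 1, 2.25, 0.2)
        a = simulate_dataset(cond, 99)
        b = simulate_dataset(cond, 99)
        np.testing.assert_array_equal(a.responses, b.responses)
        assert not np.array_equal(a.responses, simulate_dataset(cond, 100).responses)

    def test_huge_threshold_gives_all_zero(self):
        meas = GroupMeasurementParams(
            loadings=[0.6], intercepts=[0.0], thresholds=[[10.0]], unique_variances=[0.64]
        )
        cond = make_condition("negatively_skewed", 50, 2, 0, 1.0, 0.0)
        from dataclasses import replace

        cond = replace(cond, reference=meas, focal=meas)
        data = simulate_dataset(cond, 1)
        assert np.all(data.responses == 0)

    def test_binary_pooled_frequency_matches_probit(self):
        """Category-1 frequency converges to Phi(0.59) for the negatively
        skewed binary set with invariant groups."""
        cond = make_condition("negatively_skewed", 100_000, 2, 0, 1.0, 0.0)
        data = simulate_dataset(cond, 5)
        freq = data.responses.mean()
        target = ndtr(0.59)
        # item scores are correlated within person; allow a generous margin
        assert freq == pytest.approx(target, abs=0.005)

    def test_category_frequencies_match_analytic(self):
        cond = make_condition("negatively_skewed", 200_000, 5, 3, 2.25, 0.2)
        data = simulate_dataset(cond, 17)
        for group, meas, fac in [
            ("reference", cond.reference, cond.reference_factor),
            ("focal", cond.focal, cond.focal_factor),
        ]:
            y = data.group(group)
            for j in (0, 9):
                pi = category_probabilities(meas, fac, j)
                emp = np.bincount(y[:, j], minlength=5) / y.shape[0]
                se = np.sqrt(pi * (1 - pi) / y.shape[0])
                assert np.all(np.abs(emp - pi) < 4 * se + 1e-12)

    def test_simulated_skewness_matches_table(self):
        cond = make_condition("negatively_skewed", 500_000, 5, 0, 1.0, 0.0)
        data = simulate_dataset(cond, 23)
        y = data.responses[:, 0].astype(float)
        m = y.mean()
        skew = np.mean((y - m) ** 3) / np.var(y) ** 1.5
        assert skew == pytest.approx(tabulated_skewness("negatively_skewed", 5), abs=0.05)

    def test_scalar_invariant_by_construction(self):
        """Replacing focal unique variances by the reference values changes
        only the unique-factor draws: invariant items are untouched."""
        cond = make_condition("negatively_skewed", 300, 5, 3, 2.25, 0.2)
        a = simulate_dataset(cond, 7)
        b = simulate_dataset(cond.invariant_counterpart(), 7)
        np.testing.assert_array_equal(a.responses[:, :7], b.responses[:, :7])


class TestDichotomize:
    def _data(self, col):
        arr = np.tile(np.asarray(col)[:, None], (1, 2))
        return OrdinalDataset(arr, np.array(["r", "f"] * (len(col) // 2) + ["r"] * (len(col) % 2)), 5)

    def test_likert_cut_at_three(self):
        # published coding 1-5 (internal 0-4): {1,2}->0, {3,4,5}->1
        data = self._data([0, 2, 4, 1, 3])
        out = dichotomize(data, cut=3, original_base=1)
        np.testing.assert_array_equal(out.responses[:, 0], [0, 1, 1, 0, 1])
        assert out.n_categories == 2

    def test_binary_identity(self):
        data = OrdinalDataset(
            np.array([[0], [1], [1]]), np.array(["r", "r", "f"]), 2
        )
        out = dichotomize(data, cut=1)
        np.testing.assert_array_equal(out.responses, data.responses)

    def test_cut_out_of_range(self):
        data = self._data([0, 1, 2, 3, 4])
        with pytest.raises(ValueError, match="cut"):
            dichotomize(data, cut=6, original_base=1)


def test_csv_roundtrip(tmp_path):
    cond = make_condition("negatively_skewed", 30, 5, 0, 1.0, 0.0)
    data = simulate_dataset(cond, 3)
    path = tmp_path / "resp.csv"
    data.to_csv(path)
    back = OrdinalDataset.from_csv(path)
    np.testing.assert_array_equal(back.responses, data.responses)
    np.testing.assert_array_equal(back.group_labels, data.group_labels)
    assert back.n_categories == 5
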