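import numpy as np
import pytest
from scipy.special import ndtri

from ordmi import OrdinalDataset, make_condition, simulate_dataset
from ordmi.bvn import rectangle_probabilities
from ordmi.polychoric import (
    EmptyCategoryError,
    polychoric_correlation,
    summary_statistics,
    univariate_thresholds,
)


class TestUnivariateThresholds:
    def test_inverse_normal_of_cumulative_proportion(self):
        col = np.array([0] * 28 + [1] * 72)
        tau = univariate_thresholds(col, 2)
        assert tau[0] == pytest.approx(ndtri(0.28), abs=1e-12)

    def test_even_split_gives_zero(self):
        assert univariate_thresholds(np.array([0, 1] * 50), 2)[0] == 0.0

    def test_strictly_increasing(self):
        col = np.array([0] * 10 + [1] * 20 + [2] * 30 + [3] * 25 + [4] * 15)
        tau = univariate_thresholds(col, 5)
        assert np.all(np.diff(tau) > 0)

    def test_empty_category_raises(self):
        col = np.array([0, 1, 1, 3, 4, 0])
        with pytest.raises(EmptyCategoryError, match="2"):
            univariate_thresholds(col, 5)


def _columns_from_table(table):
    ci, cj = table.shape
    a, b = [], []
    for i in range(ci):
        for j in range(cj):
            a += [i] * table[i, j]
            b += [j] * table[i, j]
    return np.array(a), np.array(b)


class TestPolychoricCorrelation:
    def test_tetrachoric_arcsine_identity(self):
        """A 2x2 table with cells (1/3, 1/6, 1/6, 1/3) has P(both low)=1/3 =
        1/4 + arcsin(rho)/(2*pi), i.e. rho = 0.5 exactly."""
        n = 12000
        a, b = _columns_from_table(np.array([[n // 3, n // 6], [n // 6, n // 3]]))
        tau = np.array([0.0])
        est = polychoric_correlation(a, b, tau, tau)
        assert est.rho == pytest.approx(0.5, abs=2e-4)
        assert not est.boundary

    def test_independent_columns_give_zero(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 3, 20000)
        b = rng.integers(0, 3, 20000)
        ta = univariate_thresholds(a, 3)
        tb = univariate_thresholds(b, 3)
        est = polychoric_correlation(a, b, ta, tb)
        assert abs(est.rho) < 3 / np.sqrt(20000) * 2

    @pytest.mark.parametrize("seed,C", [(1, 2), (2, 5), (3, 7)])
    def test_matches_grid_search_oracle(self, seed, C):
        """The bounded-scalar optimum agrees with brute-force grid-search ML
        at 1e-4 resolution, within 1e-3."""
        cond = make_condition("negatively_skewed", 400, C, 0, 1.0, 0.3)
        data = simulate_dataset(cond, seed)
        y = data.group("reference")
        ta = univariate_thresholds(y[:, 0], C)
        tb = univariate_thresholds(y[:, 1], C)
        est = polychoric_correlation(y[:, 0], y[:, 1], ta, tb)
        table = np.zeros((C, C))
        np.add.at(table, (y[:, 0], y[:, 1]), 1.0)
        grid = np.arange(-0.999, 0.999, 1e-4)
        lls = np.array(
            [
                np.sum(table * np.log(np.clip(rectangle_probabilities(ta, tb, r), 1e-12, None)))
                for r in grid
            ]
        )
        assert est.rho == pytest.approx(grid[np.argmax(lls)], abs=1e-3)

    def test_reversing_category_order_flips_sign(self):
        """Order-preserving relabelings leave rho unchanged; reversing one
        margin flips its sign."""
        cond = make_condition("negatively_skewed", 1000, 5, 0, 1.0, 0.0)
        y = simulate_dataset(cond, 9).group("reference")
        a, b = y[:, 0], y[:, 1]
        ta = univariate_thresholds(a, 5)
        tb = univariate_thresholds(b, 5)
        base = polychoric_correlation(a, b, ta, tb).rho
        a_rev = 4 - a
        ta_rev = univariate_thresholds(a_rev, 5)
        flipped = polychoric_correlation(a_rev, b, ta_rev, tb).rho
        assert flipped == pytest.approx(-base, abs=1e-5)
        both = polychoric_correlation(4 - a, 4 - b, ta_rev, univariate_thresholds(4 - b, 5)).rho
        assert both == pytest.approx(base, abs=1e-5)

    def test_consistency_for_item_factor_model(self):
        """rho_hat converges to lam_i*lam_j*psi / (sd_i*sd_j) and thresholds
        to the standardized generating thresholds."""
        cond = make_condition("negatively_skewed", 100_000, 5, 0, 1.0, 0.0)
        y = simulate_dataset(cond, 12).group("reference")
        ta = univariate_thresholds(y[:, 0], 5)
        tb = univariate_thresholds(y[:, 1], 5)
        est = polychoric_correlation(y[:, 0], y[:, 1], ta, tb)
        assert est.rho == pytest.approx(0.36, abs=0.012)
        np.testing.assert_allclose(ta, [-1.55, -1.08, -0.55, 0.15], atol=0.02)


class TestSummaryStatistics:
    def test_dimensions_binary_three_items(self):
        rng = np.random.default_rng(0)
        y = (rng.normal(size=(200, 3)) > 0).astype(int)
        data = OrdinalDataset(y, np.array(["r"] * 100 + ["f"] * 100), 2)
        summ = summary_statistics(data)
        for g in ("r", "f"):
            assert summ.groups[g].stat_vector.shape == (6,)
            assert summ.groups[g].gamma.shape == (6, 6)

    def test_gamma_symmetric_psd(self, c5_invariant_summary):
        g = c5_invariant_summary.groups["reference"].gamma
        np.testing.assert_allclose(g, g.T, atol=1e-10)
        assert np.linalg.eigvalsh(g).min() > -1e-8

    def test_duplicated_rows_halve_sampling_variance(self):
        cond = make_condition("negatively_skewed", 300, 2, 0, 1.0, 0.0)
        data = simulate_dataset(cond, 31)
        doubled = OrdinalDataset(
            np.vstack([data.responses, data.responses]),
            np.concatenate([data.group_labels, data.group_labels]),
            2,
        )
        s1 = summary_statistics(data).groups["reference"]
        s2 = summary_statistics(doubled).groups["reference"]
        np.testing.assert_allclose(s1.stat_vector, s2.stat_vector, atol=1e-6)
        # per-observation Gamma is unchanged; Cov(s_hat) = Gamma/n halves
        np.testing.assert_allclose(s1.gamma, s2.gamma, atol=1e-4)
        np.testing.assert_allclose(s2.gamma / s2.n, s1.gamma / s1.n / 2, atol=1e-6)

    def test_gamma_matches_bootstrap(self):
        """Analytic sampling variances of thresholds and polychorics agree
        with a nonparametric bootstrap within 15%."""
        cond = make_condition("negatively_skewed", 5000, 2, 0, 1.0, 0.0)
        y = simulate_dataset(cond, 7).group("reference")[:, :4]
        labels = np.array(["g"] * y.shape[0])
        base = summary_statistics(OrdinalDataset(y, labels, 2)).groups["g"]
        rng = np.random.default_rng(3)
        boot = []
        for _ in range(500):
            idx = rng.integers(0, y.shape[0], y.shape[0])
            boot.append(
                summary_statistics(OrdinalDataset(y[idx], labels, 2)).groups["g"].stat_vector
            )
        boot_var = np.var(np.asarray(boot), axis=0, ddof=1)
        anal_var = np.diag(base.gamma) / base.n
        np.testing.assert_allclose(anal_var, boot_var, rtol=0.15)

    def test_empty_category_identifies_group_and_item(self):
        y = np.array([[0, 0], [1, 0], [0, 0], [1, 0]])
        data = OrdinalDataset(y, np.array(["r", "r", "f", "f"]), 2)
        with pytest.raises(EmptyCategoryError) as err:
            summary_statistics(data)
        assert err.value.item == 1
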