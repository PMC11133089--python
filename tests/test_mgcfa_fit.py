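import numpy as np
import pytest

from ordmi import make_condition, simulate_dataset, summary_statistics
from ordmi.mgcfa import build_model_spec, count_df, fit, implied_moments, wald_factor_mean
from ordmi.mgcfa.fit import (
    _numeric_jacobian,
    model_sigma,
    model_sigma_jac,
    start_values,
)
from ordmi.polychoric import GroupSummary, PolychoricSummary


class TestImpliedMoments:
    def _params(self, spec, lam, tau, theta, alpha, psi):
        return {
            "lam": np.asarray(lam, float),
            "tau": np.asarray(tau, float),
            "theta": np.asarray(theta, float),
            "alpha": np.asarray(alpha, float),
            "psi": np.asarray(psi, float),
        }

    def test_zero_loadings_identity_correlations(self):
        spec = build_model_spec("scalar", 3, 2)
        params = self._params(
            spec, np.zeros((2, 3)), np.zeros((2, 3, 1)), np.ones((2, 3)), [0, 0], [1, 1]
        )
        for tau_std, corr in implied_moments(params, spec):
            np.testing.assert_allclose(corr, np.eye(3))

    def test_unit_total_variance_returns_raw_thresholds(self):
        spec = build_model_spec("scalar", 2, 3)
        lam = np.full((2, 2), 0.6)
        theta = np.full((2, 2), 1 - 0.36)
        tau = np.tile([[-0.5, 0.7]], (2, 2, 1))
        params = self._params(spec, lam, tau, theta, [0, 0], [1, 1])
        for tau_std, corr in implied_moments(params, spec):
            np.testing.assert_allclose(tau_std, tau[0], atol=1e-12)

    def test_matches_analytic_moments_of_generating_model(self):
        """At the generating parameters the implied moments equal the
        closed-form standardized thresholds and correlations."""
        spec = build_model_spec("scalar", 10, 5)
        cond = make_condition("negatively_skewed", 100, 5, 0, 1.0, 0.2)
        lam = np.tile(cond.reference.loadings, (2, 1))
        theta = np.vstack([cond.reference.unique_variances, cond.focal.unique_variances])
        tau = np.stack([cond.reference.thresholds, cond.focal.thresholds])
        params = self._params(spec, lam, tau, theta, [0.0, 0.2], [1.0, 1.0])
        (t_r, c_r), (t_f, c_f) = implied_moments(params, spec)
        np.testing.assert_allclose(t_r, cond.reference.thresholds, atol=1e-12)
        np.testing.assert_allclose(t_f[0], (np.array([-1.55, -1.08, -0.55, 0.15]) - 0.12))
        np.testing.assert_allclose(c_r[0, 1], 0.36, atol=1e-12)

    def test_nonpositive_variance_rejected(self):
        spec = build_model_spec("scalar", 2, 2)
        params = self._params(
            spec, np.full((2, 2), 0.5), np.zeros((2, 2, 1)), np.full((2, 2), -1.0), [0, 0], [1, 1]
        )
        with pytest.raises(ValueError, match="variance"):
            implied_moments(params, spec)


def test_analytic_jacobian_matches_finite_differences():
    rng = np.random.default_rng(11)
    for stage, C, style, marker in [("scalar", 2, "lavaan", None), ("strict", 5, "liu", 1)]:
        spec = build_model_spec(stage, 6, C, marker=marker, id_style=style)
        x = rng.normal(0.4, 0.15, spec.n_free)
        for i, nm in enumerate(spec.param_names):
            if nm.startswith(("theta", "psi")):
                x[i] = abs(x[i]) + 0.5
        np.testing.assert_allclose(
            model_sigma_jac(x, spec), _numeric_jacobian(x, spec, 1e-6), atol=1e-8
        )


def _population_summary(condition, n_gamma=60_000):
    """Exact population implied moments as 'observed' statistics, with a
    Gamma estimated from one large simulated sample."""
    from ordmi.moments import category_probabilities
    from scipy.special import ndtri

    big = simulate_dataset(
        make_condition(
            condition.parameter_set,
            n_gamma,
            condition.n_categories,
            condition.n_noninvariant,
            condition.noninvariance_factor,
            condition.focal_factor_mean,
        ),
        2,
    )
    emp = summary_statistics(big)
    groups = {}
    p = condition.reference.n_items
    iu = np.triu_indices(p, k=1)
    for gname, meas, fac in [
        ("reference", condition.reference, condition.reference_factor),
        ("focal", condition.focal, condition.focal_factor),
    ]:
        tau = np.array(
            [
                ndtri(np.cumsum(category_probabilities(meas, fac, j))[:-1])
                for j in range(p)
            ]
        )
        sd = np.sqrt(meas.loadings**2 * fac.variance + meas.unique_variances)
        corr = np.outer(meas.loadings, meas.loadings) * fac.variance / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        groups[gname] = GroupSummary(
            thresholds=tau,
            correlations=corr,
            gamma=emp.groups[gname].gamma,
            n=condition.group_size,
        )
    return PolychoricSummary(groups=groups, n_items=p, n_categories=condition.n_categories)


class TestFit:
    def test_population_moments_recover_generating_parameters(self):
        """Fitting exact population moments returns the generating values
        (on the theta_r=1 scale: lambda* = 0.6/0.8 = 0.75) within 1e-4."""
        cond = make_condition("negatively_skewed", 500, 5, 3, 1.5**2, 0.2)
        summary = _population_summary(cond)
        spec = build_model_spec("scalar", 10, 5, id_style="lavaan")
        res = fit(summary, spec)
        assert res.converged
        assert res.estimate("alpha", 1) == pytest.approx(0.2, abs=1e-4)
        assert res.estimate("psi", 1) == pytest.approx(1.0, abs=1e-3)
        lam_hat = res.estimates[spec.lam_map[0]]
        np.testing.assert_allclose(lam_hat, 0.75, atol=1e-4)
        theta_f = res.estimates[spec.theta_map[1]]
        np.testing.assert_allclose(theta_f[:7], 1.0, atol=1e-3)
        np.testing.assert_allclose(theta_f[7:], 2.25, atol=1e-3)
        assert res.stat_raw == pytest.approx(0.0, abs=1e-6)

    def test_statistic_calibrated_for_correct_model(self, c5_invariant_summary):
        spec = build_model_spec("strict", 10, 5, id_style="lavaan")
        res = fit(c5_invariant_summary, spec)
        assert res.converged and not res.heywood
        assert res.df == count_df(spec)
        # a correctly specified model should not be wildly rejected
        assert res.stat_scaled < res.df + 6 * np.sqrt(2 * res.df)

    def test_nonconvergence_never_raises(self):
        """The empirically underidentified dichotomous scalar model returns
        converged=False rather than raising."""
        cond = make_condition("negatively_skewed", 100, 2, 3, 2.25, 0.0)
        # seed chosen arbitrarily; scan a few replications for a failure
        flags = []
        for seed in range(8):
            data = simulate_dataset(cond, seed)
            res = fit(summary_statistics(data), build_model_spec("scalar", 10, 2))
            flags.append(res.converged)
        assert not all(flags)

    def test_wald_requires_free_focal_mean(self, c5_invariant_summary):
        spec = build_model_spec("configural", 10, 5, id_style="lavaan")
        res = fit(c5_invariant_summary, spec)
        with pytest.raises(ValueError, match="fixed"):
            wald_factor_mean(res)

    def test_start_values_contract(self, c5_invariant_summary):
        spec = build_model_spec("strict", 10, 5, id_style="lavaan")
        x0 = start_values(spec, c5_invariant_summary)
        for name, v in zip(spec.param_names, x0):
            if name.startswith("lambda"):
                assert v == 0.7
            elif name.startswith(("psi", "theta")):
                assert v == 1.0
            elif name.startswith("alpha"):
                assert v == 0.0
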