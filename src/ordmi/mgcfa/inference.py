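"""Robust test statistics, difference tests, modification indices, fit
indices and factor-mean Wald tests for DWLS fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, ncx2, norm

from .fit import FitResult, model_sigma
from .spec import ModelSpec, build_model_spec

__all__ = [
    "robust_chisq",
    "scaled_difference_test",
    "DifferenceTest",
    "modification_indices",
    "fit_measures",
    "FitMeasures",
    "wald_factor_mean",
    "WaldResult",
    "embed_parameters",
]


def robust_chisq(result: FitResult):
    """Mean-and-variance-adjusted chi-square statistic, df and p value."""
    if not result.converged:
        raise ValueError("robust statistic requires a converged fit")
    if result.df == 0:
        return 0.0, 0, np.nan
    return result.stat_scaled, result.df, result.p_value


@dataclass
class DifferenceTest:
    statistic: float
    df: int
    p_value: float
    negative_adjustment: bool = False


def scaled_difference_test(nested: FitResult, parent: FitResult) -> DifferenceTest:
    """Scaled chi-square difference test between two nested DWLS fits.

    ``nested`` carries the additional constraints (larger df).  The raw
    discrepancy difference is rescaled so its first two moments match a
    chi-square with df equal to the constraint count; a negative adjusted
    value is floored at zero and flagged.
    """
    ddf = nested.df - parent.df
    if ddf == 0 and np.allclose(nested.s, parent.s):
        return DifferenceTest(0.0, 0, np.nan)
    if ddf <= 0:
        raise ValueError("first argument must be the more constrained (nested) model")
    if nested.s.shape != parent.s.shape or not np.allclose(nested.s, parent.s):
        raise ValueError("difference test requires fits to the same summary statistics")
    if nested.U is None or parent.U is None:
        raise ValueError("difference test requires both fits to carry inference matrices")
    Ud = nested.U - parent.U
    M = Ud @ nested.S_full
    tr1 = float(np.trace(M))
    tr2 = float(np.sum(M * M.T))
    raw = nested.stat_raw - parent.stat_raw
    negative = False
    if tr2 <= 0:
        stat = 0.0
        negative = True
    else:
        a = np.sqrt(ddf / tr2)
        b = ddf - a * tr1
        stat = a * raw + b
        if stat < 0:
            stat = 0.0
            negative = True
    return DifferenceTest(float(stat), int(ddf), float(chi2.sf(stat, ddf)), negative)


def embed_parameters(old_spec: ModelSpec, x_old: np.ndarray, new_spec: ModelSpec) -> np.ndarray:
    """Map estimates of one spec into another spec's parameter vector.

    Every slot's value under the old spec is written into the new spec's
    free vector; slot-for-slot this is exact when the new spec only splits
    (releases) equality classes of the old one.
    """
    old = {
        (kind, k, j, c): (x_old[idx] if idx >= 0 else fixed)
        for kind, k, j, c, idx, fixed in old_spec.slots()
    }
    x_new = np.zeros(new_spec.n_free)
    for kind, k, j, c, idx, _fixed in new_spec.slots():
        if idx >= 0:
            x_new[idx] = old[(kind, k, j, c)]
    return x_new


def modification_indices(result: FitResult) -> pd.DataFrame:
    """Robust 1-df score statistics for releasing each cross-group equality.

    For each releasable constraint the score direction is the derivative of
    the implied moments with respect to the freed (focal) parameter at the
    restricted solution; the statistic is g^2 / Var(g) with
    g = delta' W^-1 e_hat and Var from the full asymptotic covariance of
    the residuals.
    """
    if not result.converged:
        raise ValueError("modification indices require a converged fit")
    spec = result.spec
    tokens = spec.releasable_constraints()
    w = result.weights
    e = result.s - result.sigma_hat
    # covariance of residuals: P S P'
    info_inv = np.linalg.pinv(result.delta.T @ (result.delta / w[:, None]))
    P = np.eye(w.size) - result.delta @ info_inv @ (result.delta / w[:, None]).T
    cov_e = P @ result.S_full @ P.T
    rows = []
    for token in tokens:
        new_spec = spec.with_release(token)
        x_embed = embed_parameters(spec, result.estimates, new_spec)
        idx = new_spec.release_indices[tuple(token)]
        h = 1e-6 * max(1.0, abs(x_embed[idx]))
        xp = x_embed.copy()
        xm = x_embed.copy()
        xp[idx] += h
        xm[idx] -= h
        dcol = (model_sigma(xp, new_spec) - model_sigma(xm, new_spec)) / (2 * h)
        u = dcol / w
        g = float(u @ e)
        var_g = float(u @ cov_e @ u)
        mi = g * g / var_g if var_g > 0 else 0.0
        rows.append({"constraint": tuple(token), "mi": max(mi, 0.0)})
    return pd.DataFrame(rows, columns=["constraint", "mi"])


@dataclass
class FitMeasures:
    rmsea: float
    rmsea_ci: tuple
    cfi: float
    srmr: float


def _baseline_stat(result: FitResult):
    """Robust statistic of the independence baseline (thresholds free per
    group, zero latent-response correlations)."""
    spec = result.spec
    p, cm1 = spec.n_items, spec.n_categories - 1
    n_thr = p * cm1
    m_per = n_thr + p * (p - 1) // 2
    K = spec.n_groups
    w = result.weights
    s = result.s
    corr_mask = np.zeros(K * m_per, dtype=bool)
    for k in range(K):
        corr_mask[k * m_per + n_thr : (k + 1) * m_per] = True
    e = np.where(corr_mask, s, 0.0)
    stat_raw = float(e @ (e / w))
    df_b = int(corr_mask.sum())
    U = np.zeros((w.size, w.size))
    U[corr_mask, corr_mask] = 1.0 / w[corr_mask]
    M = U @ result.S_full
    tr1 = float(np.trace(M))
    tr2 = float(np.sum(M * M.T))
    a = np.sqrt(df_b / tr2)
    b = df_b - a * tr1
    return max(a * stat_raw + b, 0.0), df_b


def fit_measures(result: FitResult, ci_level: float = 0.95) -> FitMeasures:
    """RMSEA (with noncentral chi-square CI), CFI against the independence
    baseline, and SRMR from summary-statistic residuals."""
    if not result.converged:
        raise ValueError("fit measures require a converged fit")
    T, df = result.stat_scaled, result.df
    N = result.n_total
    if df <= 0:
        raise ValueError("fit measures require df > 0")
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * N)))

    def _ncp(prob):
        # noncentrality lambda with P(X <= T | df, lambda) = prob
        if ncx2.cdf(T, df, 0.0) < prob:
            return 0.0
        lo, hi = 0.0, max(10.0, 2 * T)
        while ncx2.cdf(T, df, hi) > prob:
            hi *= 2
            if hi > 1e8:
                break
        for _ in range(200):
            mid = (lo + hi) / 2
            if ncx2.cdf(T, df, mid) > prob:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    tail = (1.0 - ci_level) / 2.0
    lam_lo = _ncp(1.0 - tail)
    lam_hi = _ncp(tail)
    ci = (
        float(np.sqrt(lam_lo / (df * N))),
        float(np.sqrt(lam_hi / (df * N))),
    )
    T_b, df_b = _baseline_stat(result)
    denom = max(T_b - df_b, T - df, 0.0)
    cfi = 1.0 - max(T - df, 0.0) / denom if denom > 0 else 1.0
    srmr = float(np.sqrt(np.mean((result.s - result.sigma_hat) ** 2)))
    return FitMeasures(rmsea=rmsea, rmsea_ci=ci, cfi=float(np.clip(cfi, 0.0, 1.0)), srmr=srmr)


@dataclass
class WaldResult:
    estimate: float
    se: float
    z: float
    p_value: float
    ci: tuple

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def wald_factor_mean(result: FitResult, ci_level: float = 0.95) -> WaldResult:
    """Wald z-test of the focal-group factor mean (the latent mean
    difference, since the reference mean is fixed at zero)."""
    spec = result.spec
    if spec.alpha_map[-1] < 0:
        raise ValueError("the focal factor mean is fixed in this spec")
    idx = int(spec.alpha_map[-1])
    est = float(result.estimates[idx])
    se = float(result.se[idx])
    z = est / se if se > 0 else np.nan
    crit = norm.ppf(0.5 + ci_level / 2.0)
    return WaldResult(
        estimate=est,
        se=se,
        z=z,
        p_value=float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        ci=(est - crit * se, est + crit * se),
    )
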