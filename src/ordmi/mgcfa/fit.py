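"""Diagonally weighted least squares estimation of ordinal CFA models.

The model is fit to stage-one summary statistics s (standardized
thresholds, then lower-triangle polychoric correlations, stacked over
groups) by minimizing

    F(x) = (s - sigma(x))' W^-1 (s - sigma(x)),

where W = diag(Cov(s_hat)) holds the estimated sampling variances of the
summary statistics (the "diagonal weights").  Standard errors use the full
asymptotic covariance in the usual sandwich form, and the robust test
statistic is the mean-and-variance-adjusted (scaled-and-shifted) quadratic
form whose first two moments match the chi-square with the model df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2

from ..polychoric import PolychoricSummary
from .spec import ModelSpec, count_df

__all__ = ["FitOptions", "FitResult", "implied_moments", "fit", "model_sigma"]

_VAR_FLOOR = 1e-10


def implied_moments(params: dict, spec: ModelSpec) -> list:
    """Model-implied standardized thresholds and latent-response correlations.

    ``params`` as produced by :meth:`ModelSpec.assemble` (keys lam, tau,
    theta, alpha, psi).  Returns one ``(tau_std, corr)`` tuple per group,
    with tau_std = (tau - lam*alpha) / sqrt(lam^2*psi + theta) and
    corr_ij = lam_i*lam_j*psi / (sd_i*sd_j).
    """
    out = []
    for k in range(spec.n_groups):
        lam = params["lam"][k]
        theta = params["theta"][k]
        psi = params["psi"][k]
        alpha = params["alpha"][k]
        var = lam**2 * psi + theta
        if np.any(var <= 0):
            raise ValueError("nonpositive implied latent-response variance")
        sd = np.sqrt(var)
        tau_std = (params["tau"][k] - (lam * alpha)[:, None]) / sd[:, None]
        corr = np.outer(lam, lam) * psi / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        out.append((tau_std, corr))
    return out


def model_sigma(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Flat implied-moment vector in summary-statistic order (clipping
    nonpositive implied variances so optimizers can traverse bad regions)."""
    params = spec.assemble(x)
    p = spec.n_items
    iu = np.triu_indices(p, k=1)
    pieces = []
    for k in range(spec.n_groups):
        lam = params["lam"][k]
        theta = params["theta"][k]
        psi = params["psi"][k]
        alpha = params["alpha"][k]
        sd = np.sqrt(np.clip(lam**2 * psi + theta, _VAR_FLOOR, None))
        tau_std = (params["tau"][k] - (lam * alpha)[:, None]) / sd[:, None]
        corr = np.outer(lam, lam) * np.clip(psi, -1e6, 1e6) / np.outer(sd, sd)
        pieces.append(tau_std.ravel())
        pieces.append(corr[iu])
    return np.concatenate(pieces)


@dataclass
class FitOptions:
    max_iter: int = 500
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-10
    rel_grad_tol: float = 1e-6
    info_rcond: float = 1e-8
    fd_step: float = 1e-6


@dataclass
class FitResult:
    """Estimates, robust inference ingredients, and status of one DWLS fit."""

    spec: ModelSpec
    estimates: np.ndarray
    se: np.ndarray
    discrepancy: float
    stat_raw: float
    stat_scaled: float
    df: int
    scale: float
    shift: float
    p_value: float
    converged: bool
    heywood: bool
    message: str
    group_sizes: dict
    s: np.ndarray = field(repr=False, default=None)
    sigma_hat: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)
    S_full: np.ndarray = field(repr=False, default=None)
    delta: np.ndarray = field(repr=False, default=None)
    U: np.ndarray = field(repr=False, default=None)
    cov_params: np.ndarray = field(repr=False, default=None)
    summary: PolychoricSummary = field(repr=False, default=None)

    def estimate(self, kind, group=1, item=None, cat=None) -> float:
        idx = self.spec.free_index(kind, group, item, cat)
        return float(self.estimates[idx])

    def standard_error(self, kind, group=1, item=None, cat=None) -> float:
        idx = self.spec.free_index(kind, group, item, cat)
        return float(self.se[idx])

    def parameter_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.spec.param_names,
                "estimate": self.estimates,
                "se": self.se,
            }
        )

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes.values()))

    def to_dict(self) -> dict:
        return {
            "stage": self.spec.stage,
            "id_style": self.spec.id_style,
            "released": [list(t) for t in self.spec.released],
            "converged": bool(self.converged),
            "heywood": bool(self.heywood),
            "df": int(self.df),
            "stat_scaled": float(self.stat_scaled),
            "p_value": float(self.p_value) if np.isfinite(self.p_value) else None,
            "estimates": {
                name: [float(est), float(se)]
                for name, est, se in zip(self.spec.param_names, self.estimates, self.se)
            },
        }


def model_sigma_jac(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Analytic Jacobian of :func:`model_sigma` with respect to the free
    parameters (rows in summary-statistic order)."""
    params = spec.assemble(x)
    p = spec.n_items
    cm1 = spec.n_categories - 1
    iu, ju = np.triu_indices(p, k=1)
    n_pairs = iu.size
    m_per = p * cm1 + n_pairs
    J = np.zeros((spec.n_groups * m_per, spec.n_free))
    for k in range(spec.n_groups):
        lam = params["lam"][k]
        tau = params["tau"][k]
        theta = params["theta"][k]
        alpha = params["alpha"][k]
        psi = params["psi"][k]
        var = np.clip(lam**2 * psi + theta, _VAR_FLOOR, None)
        sd = np.sqrt(var)
        tstar = (tau - (lam * alpha)[:, None]) / sd[:, None]
        rho = lam[iu] * lam[ju] * psi / (sd[iu] * sd[ju])
        base = k * m_per

        def add(rows, col_map, vals):
            # accumulate d sigma[rows] / d x[col_map] for free parameters
            if np.ndim(col_map) == 0:
                if col_map >= 0:
                    J[rows, col_map] += vals
                return
            mask = col_map >= 0
            np.add.at(J, (rows[mask], col_map[mask]), np.asarray(vals)[mask])

        thr_rows = base + np.arange(p * cm1).reshape(p, cm1)
        # d tau*/d tau = 1/sd
        add(thr_rows.ravel(), spec.tau_map[k].ravel(),
            np.repeat(1.0 / sd, cm1))
        # d tau*/d lambda
        dlam = (-alpha / sd)[:, None] - tstar * (lam * psi / var)[:, None]
        add(thr_rows.ravel(), np.repeat(spec.lam_map[k], cm1), dlam.ravel())
        # d tau*/d theta
        dth = -tstar / (2 * var)[:, None]
        add(thr_rows.ravel(), np.repeat(spec.theta_map[k], cm1), dth.ravel())
        # d tau*/d alpha and d psi (scalar params)
        if spec.alpha_map[k] >= 0:
            J[thr_rows.ravel(), spec.alpha_map[k]] += np.repeat(-lam / sd, cm1)
        if spec.psi_map[k] >= 0:
            J[thr_rows.ravel(), spec.psi_map[k]] += (
                -tstar * (lam**2 / (2 * var))[:, None]
            ).ravel()

        pair_rows = base + p * cm1 + np.arange(n_pairs)
        # d rho/d lambda_i and lambda_j
        drho_di = lam[ju] * psi / (sd[iu] * sd[ju]) - rho * lam[iu] * psi / var[iu]
        drho_dj = lam[iu] * psi / (sd[iu] * sd[ju]) - rho * lam[ju] * psi / var[ju]
        add(pair_rows, spec.lam_map[k][iu], drho_di)
        add(pair_rows, spec.lam_map[k][ju], drho_dj)
        # d rho/d theta
        add(pair_rows, spec.theta_map[k][iu], -rho / (2 * var[iu]))
        add(pair_rows, spec.theta_map[k][ju], -rho / (2 * var[ju]))
        if spec.psi_map[k] >= 0:
            dpsi = lam[iu] * lam[ju] / (sd[iu] * sd[ju]) - rho * (
                lam[iu] ** 2 / (2 * var[iu]) + lam[ju] ** 2 / (2 * var[ju])
            )
            J[pair_rows, spec.psi_map[k]] += dpsi
    return J


def _numeric_jacobian(x, spec, step):
    n = x.size
    cols = []
    for i in range(n):
        h = step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        cols.append((model_sigma(xp, spec) - model_sigma(xm, spec)) / (2 * h))
    return np.column_stack(cols) if cols else np.zeros((spec.n_moments, 0))


def start_values(spec: ModelSpec, summary: PolychoricSummary) -> np.ndarray:
    """Loadings 0.7, unique variances 1, factor mean 0, variance 1;
    thresholds at the stage-one estimates (group mean where equated)."""
    x0 = np.zeros(spec.n_free)
    counts = np.zeros(spec.n_free)
    for name, idx in zip(spec.param_names, range(spec.n_free)):
        if name.startswith("lambda"):
            x0[idx] = 0.7
        elif name.startswith("theta") or name.startswith("psi"):
            x0[idx] = 1.0
    group_taus = [summary.groups[g].thresholds for g in summary.group_names]
    acc = np.zeros(spec.n_free)
    for k in range(spec.n_groups):
        tau_k = group_taus[min(k, len(group_taus) - 1)]
        for j in range(spec.n_items):
            for c in range(spec.n_categories - 1):
                idx = spec.tau_map[k, j, c]
                if idx >= 0:
                    acc[idx] += tau_k[j, c]
                    counts[idx] += 1
    m = counts > 0
    x0[m] = acc[m] / counts[m]
    return x0


def _scaled_shifted(stat_raw, df, U, S):
    """Mean-and-variance adjustment: a*T + b with E=df, Var=2*df."""
    if df <= 0:
        return 0.0, 1.0, 0.0, np.nan
    M = U @ S
    tr1 = float(np.trace(M))
    tr2 = float(np.sum(M * M.T))
    if tr2 <= 0:
        return float(stat_raw), 1.0, 0.0, np.nan
    a = np.sqrt(df / tr2)
    b = df - a * tr1
    stat = max(a * stat_raw + b, 0.0)
    return stat, a, b, float(chi2.sf(stat, df))


def fit(
    summary: PolychoricSummary,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a model spec to stage-one summaries by DWLS.

    Nonconvergence (optimizer failure, Heywood estimates, numerically
    singular information matrix) is reported through ``converged`` /
    ``heywood`` on the result, never raised.
    """
    if not spec.fittable:
        raise ValueError("spec carries no parameter maps (bookkeeping-only spec)")
    opts = options or FitOptions()
    gnames = summary.group_names
    if len(gnames) != spec.n_groups:
        raise ValueError("summary and spec disagree on the number of groups")
    s = np.concatenate([summary.groups[g].stat_vector for g in gnames])
    ns = {g: summary.groups[g].n for g in gnames}
    w = np.concatenate(
        [np.diag(summary.groups[g].gamma) / summary.groups[g].n for g in gnames]
    )
    w = np.clip(w, _VAR_FLOOR, None)
    sqw = np.sqrt(w)
    df = count_df(spec)

    def resid(x):
        return (model_sigma(x, spec) - s) / sqw

    def jac(x):
        return model_sigma_jac(x, spec) / sqw[:, None]

    x0 = start_values(spec, summary)
    try:
        res = least_squares(
            resid,
            x0,
            jac=jac,
            method="trf",
            xtol=opts.xtol,
            ftol=opts.ftol,
            gtol=opts.gtol,
            max_nfev=opts.max_iter,
        )
        ok = bool(res.success)
        x_hat = res.x
        message = res.message
    except Exception as err:  # pragma: no cover - defensive
        ok = False
        x_hat = x0
        message = f"optimizer error: {err}"

    params = spec.assemble(x_hat)
    sigma_hat = model_sigma(x_hat, spec)
    e = s - sigma_hat
    F_val = float(e @ (e / w))

    # admissibility: free unique variances / factor variances positive,
    # implied latent-response variances positive
    heywood = False
    for k in range(spec.n_groups):
        if np.any(params["theta"][k][spec.theta_map[k] >= 0] <= 0):
            heywood = True
        if spec.psi_map[k] >= 0 and params["psi"][k] <= 0:
            heywood = True
        if np.any(params["lam"][k] ** 2 * params["psi"][k] + params["theta"][k] <= 0):
            heywood = True

    S_blocks = [summary.groups[g].gamma / summary.groups[g].n for g in gnames]
    m_per = [b.shape[0] for b in S_blocks]
    S = np.zeros((sum(m_per), sum(m_per)))
    off = 0
    for b in S_blocks:
        S[off : off + b.shape[0], off : off + b.shape[0]] = b
        off += b.shape[0]

    delta = model_sigma_jac(x_hat, spec)
    Winv_delta = delta / w[:, None]
    info = delta.T @ Winv_delta
    se = np.full(spec.n_free, np.nan)
    cov = None
    U = None
    singular = False
    if spec.n_free:
        rc = np.linalg.cond(info) if info.size else np.inf
        if not np.isfinite(rc) or 1.0 / rc < opts.info_rcond:
            singular = True
        else:
            info_inv = np.linalg.inv(info)
            bread = info_inv @ Winv_delta.T
            cov = bread @ S @ bread.T
            dvar = np.diag(cov)
            if np.any(dvar < 0):
                singular = True
            else:
                se = np.sqrt(dvar)
            U = np.diag(1.0 / w) - Winv_delta @ info_inv @ Winv_delta.T
    else:
        U = np.diag(1.0 / w)

    # relative gradient at the solution, scaled by the curvature
    if spec.n_free:
        grad = 2.0 * (delta.T @ (-e / w))
        curv = max(1.0, float(np.max(np.abs(np.diag(info)))))
        grad_ok = float(np.max(np.abs(grad))) <= opts.rel_grad_tol * curv
    else:
        grad_ok = True

    converged = ok and not heywood and not singular and grad_ok

    if U is not None and df > 0:
        stat_scaled, a, b_shift, p_val = _scaled_shifted(F_val, df, U, S)
    else:
        stat_scaled, a, b_shift, p_val = (0.0 if df == 0 else np.nan), 1.0, 0.0, np.nan

    return FitResult(
        spec=spec,
        estimates=x_hat,
        se=se,
        discrepancy=F_val,
        stat_raw=F_val,
        stat_scaled=stat_scaled,
        df=df,
        scale=a,
        shift=b_shift,
        p_value=p_val,
        converged=converged,
        heywood=heywood,
        message=message,
        group_sizes=ns,
        s=s,
        sigma_hat=sigma_hat,
        weights=w,
        S_full=S,
        delta=delta,
        U=U,
        cov_params=cov,
        summary=summary,
    )
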