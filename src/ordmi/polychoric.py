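"""Stage-one estimation for ordinal CFA.

Univariate thresholds by inverse-normal transforms of cumulative
proportions, pairwise polychoric correlations by two-stage maximum
likelihood (thresholds held fixed, multinomial likelihood over
bivariate-normal rectangle probabilities), and the joint asymptotic
covariance of the stacked summary statistics by the estimating-equation
(influence-function) sandwich.  These are the ingredients of the
diagonally-weighted least squares fits in :mod:`ordmi.mgcfa`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .bvn import bvn_pdf, rectangle_probabilities
from .datasets import OrdinalDataset

__all__ = [
    "EmptyCategoryError",
    "univariate_thresholds",
    "polychoric_correlation",
    "summary_statistics",
    "GroupSummary",
    "PolychoricSummary",
]

_RHO_BOUND = 0.999
_PROB_FLOOR = 1e-12


class EmptyCategoryError(ValueError):
    """A response category was never observed, so stage-one statistics are
    undefined (such replications are counted as nonconvergent)."""

    def __init__(self, message, group=None, item=None):
        super().__init__(message)
        self.group = group
        self.item = item


def univariate_thresholds(column: np.ndarray, n_categories: int) -> np.ndarray:
    """ML thresholds of one ordinal item: Phi^-1 of cumulative proportions."""
    column = np.asarray(column)
    counts = np.bincount(column, minlength=n_categories)
    if counts.size > n_categories or np.any(counts == 0):
        missing = [c for c in range(n_categories) if c >= counts.size or counts[c] == 0]
        raise EmptyCategoryError(
            f"empty response category {missing} (of {n_categories})", item=None
        )
    cum = np.cumsum(counts)[:-1] / column.size
    return ndtri(cum)


@dataclass
class PolychoricCorrelation:
    rho: float
    loglik: float
    boundary: bool = False


def _pair_table(col_i, col_j, c_i, c_j) -> np.ndarray:
    idx = np.asarray(col_i) * c_j + np.asarray(col_j)
    return np.bincount(idx, minlength=c_i * c_j).reshape(c_i, c_j).astype(float)


def _make_cell_probs(tau_i, tau_j):
    """Closure computing cell probabilities for fixed thresholds; marginal
    CDF values are cached so each rho evaluation costs one interior
    bivariate-CDF grid."""
    from .bvn import _bvnu

    a = np.asarray(tau_i, float)
    b = np.asarray(tau_j, float)
    Fa = ndtr(a)
    Fb = ndtr(b)
    ci, cj = a.size + 1, b.size + 1
    F = np.zeros((ci + 1, cj + 1))
    F[-1, 1:-1] = Fb
    F[1:-1, -1] = Fa
    F[-1, -1] = 1.0
    neg_a = -a[:, None]
    neg_b = -b[None, :]

    def cells(rho):
        F[1:-1, 1:-1] = _bvnu(neg_a, neg_b, rho)
        return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]

    return cells


def polychoric_correlation(
    col_i: np.ndarray,
    col_j: np.ndarray,
    thresholds_i: np.ndarray,
    thresholds_j: np.ndarray,
) -> PolychoricCorrelation:
    """Two-stage ML polychoric correlation with thresholds held fixed.

    Maximizes the multinomial likelihood of the observed contingency table
    over rho in (-0.999, 0.999); cell probabilities are bivariate-normal
    rectangle integrals.
    """
    c_i = len(thresholds_i) + 1
    c_j = len(thresholds_j) + 1
    table = _pair_table(col_i, col_j, c_i, c_j)
    if np.count_nonzero(table.sum(axis=1)) < 2 or np.count_nonzero(table.sum(axis=0)) < 2:
        raise EmptyCategoryError("contingency table is degenerate (single row/column)")
    cells = _make_cell_probs(thresholds_i, thresholds_j)

    def nll(rho):
        return -np.sum(table * np.log(np.clip(cells(rho), _PROB_FLOOR, None)))

    res = minimize_scalar(
        nll,
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    return PolychoricCorrelation(
        rho=rho, loglik=float(-res.fun), boundary=abs(rho) >= _RHO_BOUND - 1e-3
    )


# --- influence functions -------------------------------------------------

def _threshold_influence(column, tau, n_categories):
    """(n, C-1) influence matrix of one item's threshold estimates."""
    cum = ndtr(tau)
    ind = column[:, None] <= np.arange(n_categories - 1)[None, :]
    return (ind - cum) / norm.pdf(tau)


def _pair_quantities(rho, tau_i, tau_j):
    """Model cell probabilities, drho-derivative table, and dtau-derivative
    summaries for one pair at the stage-one estimates."""
    a = np.concatenate(([-np.inf], tau_i, [np.inf]))
    b = np.concatenate(([-np.inf], tau_j, [np.inf]))
    pi = np.clip(rectangle_probabilities(tau_i, tau_j, rho), _PROB_FLOOR, None)
    # d pi / d rho by inclusion-exclusion of the bivariate density at corners
    D = (
        bvn_pdf(a[1:, None], b[None, 1:], rho)
        - bvn_pdf(a[:-1, None], b[None, 1:], rho)
        - bvn_pdf(a[1:, None], b[None, :-1], rho)
        + bvn_pdf(a[:-1, None], b[None, :-1], rho)
    )
    q = np.sqrt(1.0 - rho * rho)

    def edge_terms(edges_own, edges_other):
        # g[m, b] = phi(tau_m) * (Phi((B_{b+1}-rho tau_m)/q) - Phi((B_b - rho tau_m)/q))
        tm = edges_own[1:-1][:, None]
        z = (edges_other[None, :] - rho * tm) / q
        cdf = ndtr(z)  # ndtr maps -inf/+inf edges to 0/1
        return norm.pdf(tm) * (cdf[:, 1:] - cdf[:, :-1])

    g_i = edge_terms(a, b)  # (C_i-1, C_j) effect of tau_i^(m) on row cells
    g_j = edge_terms(b, a)  # (C_j-1, C_i)
    return pi, D, g_i, g_j


def _pair_influence(col_i, col_j, tau_i, tau_j, rho, if_tau_i, if_tau_j):
    """(n,) influence values of the two-stage polychoric estimate."""
    pi, D, g_i, g_j = _pair_quantities(rho, tau_i, tau_j)
    score_tab = D / pi
    h_rr = np.sum(D * D / pi)
    # cross-information with the two items' thresholds
    ratios = D / pi  # (C_i, C_j)
    h_ri = np.sum((ratios[:-1, :] - ratios[1:, :]) * g_i, axis=1)  # (C_i-1,)
    h_rj = np.sum((ratios[:, :-1] - ratios[:, 1:]).T * g_j, axis=1)  # (C_j-1,)
    score = score_tab[col_i, col_j]
    return (score - if_tau_i @ h_ri - if_tau_j @ h_rj) / h_rr


@dataclass
class GroupSummary:
    """Stage-one summaries of one group.

    ``gamma`` is the per-observation asymptotic covariance of the stacked
    statistic vector (thresholds then lower-triangle correlations):
    Cov(s_hat) is approximately ``gamma / n``.
    """

    thresholds: np.ndarray
    correlations: np.ndarray
    gamma: np.ndarray
    n: int
    boundary_pairs: list = field(default_factory=list)

    @property
    def stat_vector(self) -> np.ndarray:
        p = self.correlations.shape[0]
        iu = np.triu_indices(p, k=1)
        return np.concatenate([self.thresholds.ravel(), self.correlations[iu]])

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "thresholds": self.thresholds.tolist(),
            "correlations": self.correlations.tolist(),
            "gamma": self.gamma.tolist(),
            "boundary_pairs": [list(map(int, bp)) for bp in self.boundary_pairs],
        }


@dataclass
class PolychoricSummary:
    """Per-group stage-one summaries for a (possibly multigroup) dataset."""

    groups: dict
    n_items: int
    n_categories: int

    @property
    def group_names(self) -> tuple:
        return tuple(self.groups)

    @property
    def n_stats_per_group(self) -> int:
        p, c = self.n_items, self.n_categories
        return p * (c - 1) + p * (p - 1) // 2

    def to_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "n_categories": self.n_categories,
            "groups": {str(g): s.to_dict() for g, s in self.groups.items()},
        }


def _group_summary(y: np.ndarray, n_categories: int, group_name=None) -> GroupSummary:
    n, p = y.shape
    c = n_categories
    tau = np.empty((p, c - 1))
    for j in range(p):
        try:
            tau[j] = univariate_thresholds(y[:, j], c)
        except EmptyCategoryError as err:
            raise EmptyCategoryError(str(err), group=group_name, item=j) from None
    if_tau = [_threshold_influence(y[:, j], tau[j], c) for j in range(p)]

    corr = np.eye(p)
    n_pairs = p * (p - 1) // 2
    if_mat = np.empty((n, p * (c - 1) + n_pairs))
    for j in range(p):
        if_mat[:, j * (c - 1) : (j + 1) * (c - 1)] = if_tau[j]
    boundary = []
    k = p * (c - 1)
    for i in range(p):
        for j in range(i + 1, p):
            est = polychoric_correlation(y[:, i], y[:, j], tau[i], tau[j])
            corr[i, j] = corr[j, i] = est.rho
            if est.boundary:
                boundary.append((i, j))
            rho_in = np.clip(est.rho, -_RHO_BOUND, _RHO_BOUND)
            if_mat[:, k] = _pair_influence(
                y[:, i], y[:, j], tau[i], tau[j], rho_in, if_tau[i], if_tau[j]
            )
            k += 1
    centered = if_mat - if_mat.mean(axis=0)
    gamma = centered.T @ centered / n
    return GroupSummary(
        thresholds=tau, correlations=corr, gamma=gamma, n=n, boundary_pairs=boundary
    )


def summary_statistics(data: OrdinalDataset, pooled: bool = False) -> PolychoricSummary:
    """Stage-one statistics (thresholds, polychorics, Gamma) per group.

    With ``pooled=True`` the group labels are ignored and a single pooled
    summary is produced (used for marker selection).
    """
    groups = {}
    if pooled:
        groups["pooled"] = _group_summary(data.responses, data.n_categories, "pooled")
    else:
        for g in data.groups:
            groups[g] = _group_summary(data.group(g), data.n_categories, g)
    return PolychoricSummary(
        groups=groups, n_items=data.n_items, n_categories=data.n_categories
    )
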