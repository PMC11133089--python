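"""Generating-model parameters for two-group ordinal item factor models.

The probit item factor model underlying everything here is

    Y*_ij = nu_j + lambda_j * eta_i + eps_ij,   eps_ij ~ N(0, theta_j),
    eta_i ~ N(alpha_k, psi_k),

with the observed ordinal response obtained by cutting the latent response
Y* at item-specific strictly increasing thresholds tau_j^(1..C-1).

Three canonical parameter sets ship with the package: ten identical items
with negatively or positively skewed response distributions, and a
seven-item set modelled on the Helpful subscale of the Beliefs About Crying
Scale (BACS).  For the BACS set the tabulated thresholds are on the
standardized latent-response scale (they reproduce the published
endorsement proportions through Phi(tau)); the loader converts them to the
raw Eq. scale used for generation.  For the skewed sets the two scales
coincide because lambda^2*psi + theta = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "GroupMeasurementParams",
    "FactorParams",
    "PopulationCondition",
    "PARAMETER_SETS",
    "load_parameter_set",
    "make_condition",
]

PARAMETER_SETS = ("negatively_skewed", "positively_skewed", "BACS")


@dataclass(frozen=True)
class GroupMeasurementParams:
    """Per-item measurement parameters of one group.

    ``thresholds`` is a (p, C-1) array on the raw latent-response scale;
    ``thresholds_std`` holds the standardized-scale values as tabulated
    (equal to ``thresholds`` when the reference latent responses have unit
    variance).
    """

    loadings: np.ndarray
    intercepts: np.ndarray
    thresholds: np.ndarray
    unique_variances: np.ndarray
    thresholds_std: np.ndarray = field(default=None)

    def __post_init__(self):
        lam = np.atleast_1d(np.asarray(self.loadings, float))
        nu = np.atleast_1d(np.asarray(self.intercepts, float))
        tau = np.atleast_2d(np.asarray(self.thresholds, float))
        th = np.atleast_1d(np.asarray(self.unique_variances, float))
        if not (lam.shape[0] == nu.shape[0] == tau.shape[0] == th.shape[0]):
            raise ValueError("parameter arrays disagree on the item count")
        if np.any(th <= 0):
            raise ValueError("unique variances must be positive")
        if tau.shape[1] and np.any(np.diff(tau, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        object.__setattr__(self, "loadings", lam)
        object.__setattr__(self, "intercepts", nu)
        object.__setattr__(self, "thresholds", tau)
        object.__setattr__(self, "unique_variances", th)
        if self.thresholds_std is None:
            object.__setattr__(self, "thresholds_std", tau)
        else:
            object.__setattr__(
                self, "thresholds_std", np.atleast_2d(np.asarray(self.thresholds_std, float))
            )

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1


@dataclass(frozen=True)
class FactorParams:
    """Latent common-factor mean and variance of one group."""

    mean: float = 0.0
    variance: float = 1.0

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("factor variance must be positive")


@dataclass(frozen=True)
class PopulationCondition:
    """A complete two-group generating model plus its design-factor labels."""

    reference: GroupMeasurementParams
    focal: GroupMeasurementParams
    reference_factor: FactorParams
    focal_factor: FactorParams
    group_size: int
    n_categories: int
    n_noninvariant: int
    noninvariance_factor: float
    focal_factor_mean: float
    parameter_set: str = ""

    @property
    def noninvariant_items(self) -> np.ndarray:
        """Indices of the designated unique-variance noninvariant items."""
        p = self.reference.n_items
        return np.arange(p - self.n_noninvariant, p)

    def invariant_counterpart(self) -> "PopulationCondition":
        """The same condition with focal unique variances reset to the
        reference values (the strict-invariant benchmark)."""
        focal = replace(self.focal, unique_variances=self.reference.unique_variances.copy())
        return replace(self, focal=focal, n_noninvariant=0, noninvariance_factor=1.0)


def _table() -> dict:
    with resources.files("ordmi.resources").joinpath("table_params.json").open() as fh:
        return json.load(fh)


def load_parameter_set(name: str, n_categories: int) -> GroupMeasurementParams:
    """Reference-group measurement parameters of a shipped parameter set.

    Parameters
    ----------
    name:
        one of ``negatively_skewed``, ``positively_skewed``, ``BACS``.
    n_categories:
        number of response categories (2, 5 or 7 for the skewed sets;
        2 or 5 for BACS).
    """
    if name not in PARAMETER_SETS:
        raise ValueError(f"unknown parameter set {name!r}; valid sets: {PARAMETER_SETS}")
    block = _table()[name]
    key = str(int(n_categories))
    if key not in block:
        valid = sorted(int(k) for k in block if k.isdigit())
        raise ValueError(f"parameter set {name!r} has no C={n_categories} variant (valid: {valid})")
    entry = block[key]
    lam = np.asarray(entry["loadings"], float)
    theta = np.asarray(entry["unique_variances"], float)
    tau_std = np.asarray(entry["thresholds"], float)
    if block["thresholds_standardized"]:
        scale = np.sqrt(lam**2 * 1.0 + theta)  # reference psi = 1
        tau_raw = tau_std * scale[:, None]
    else:
        tau_raw = tau_std
    return GroupMeasurementParams(
        loadings=lam,
        intercepts=np.zeros_like(lam),
        thresholds=tau_raw,
        unique_variances=theta,
        thresholds_std=tau_std,
    )


def tabulated_skewness(name: str, n_categories: int):
    """Skewness column of the shipped table (None where not applicable)."""
    return _table()[name][str(int(n_categories))]["skewness"]


def make_condition(
    parameter_set: str,
    group_size: int,
    n_categories: int,
    n_noninvariant: int,
    noninvariance_factor: float,
    focal_factor_mean: float,
) -> PopulationCondition:
    """Assemble a simulation condition from its design factors.

    The focal group shares the reference loadings, intercepts and
    thresholds (data are generated scalar invariant); its unique variances
    equal ``noninvariance_factor`` times the reference values on the *last*
    ``n_noninvariant`` items and are equal elsewhere.
    """
    ref = load_parameter_set(parameter_set, n_categories)
    if n_noninvariant > ref.n_items:
        raise ValueError(
            f"n_noninvariant={n_noninvariant} exceeds the item count {ref.n_items}"
        )
    if n_noninvariant < 0:
        raise ValueError("n_noninvariant must be nonnegative")
    theta_f = ref.unique_variances.copy()
    if n_noninvariant:
        theta_f[-n_noninvariant:] *= noninvariance_factor
    focal = replace(ref, unique_variances=theta_f)
    return PopulationCondition(
        reference=ref,
        focal=focal,
        reference_factor=FactorParams(0.0, 1.0),
        focal_factor=FactorParams(focal_factor_mean, 1.0),
        group_size=int(group_size),
        n_categories=int(n_categories),
        n_noninvariant=int(n_noninvariant),
        noninvariance_factor=float(noninvariance_factor),
        focal_factor_mean=float(focal_factor_mean),
        parameter_set=parameter_set,
    )
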