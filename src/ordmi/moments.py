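"""Closed-form observed-score moments under the probit item factor model.

Marginally over the factor, the latent response of item j in group k is
normal with mean nu_j + lambda_j * alpha_k and variance
lambda_j^2 * psi_k + theta_jk, so every observed-category probability is a
difference of two normal CDF values.  These formulas give the population
category distributions behind the shipped parameter tables, and the exact
observed-mean bias that unique-factor noninvariance induces when groups are
compared on raw scale scores.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .params import FactorParams, GroupMeasurementParams, PopulationCondition

__all__ = [
    "category_probabilities",
    "expected_item_mean",
    "distribution_skewness",
    "expected_scale_score",
    "population_observed_mean_difference",
    "observed_mean_bias",
]


def category_probabilities(
    item: GroupMeasurementParams, factor: FactorParams, item_index: int = 0
) -> np.ndarray:
    """Marginal observed-category distribution of a single item.

    pi_c = Phi((tau^(c+1) - nu - lambda*alpha)/s) - Phi((tau^(c) - ...)/s)
    with s = sqrt(lambda^2*psi + theta).
    """
    j = item_index
    tau = item.thresholds[j]
    if tau.size > 1 and np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    lam = item.loadings[j]
    nu = item.intercepts[j]
    theta = item.unique_variances[j]
    s = np.sqrt(lam**2 * factor.variance + theta)
    z = (tau - nu - lam * factor.mean) / s
    cum = np.concatenate(([0.0], ndtr(z), [1.0]))
    return np.diff(cum)


def expected_item_mean(dist: np.ndarray) -> float:
    """Expected score sum_c c*pi_c on the 0..C-1 coding."""
    dist = np.asarray(dist, float)
    return float(np.dot(np.arange(dist.size), dist))


def distribution_skewness(dist: np.ndarray) -> float:
    """Standardized third central moment of a discrete score distribution."""
    dist = np.asarray(dist, float)
    c = np.arange(dist.size)
    mu = np.dot(c, dist)
    var = np.dot((c - mu) ** 2, dist)
    if var <= 0:
        raise ValueError("degenerate distribution has no skewness")
    m3 = np.dot((c - mu) ** 3, dist)
    return float(m3 / var**1.5)


def expected_scale_score(meas: GroupMeasurementParams, factor: FactorParams) -> float:
    """Population mean of the per-person scale score (mean of item scores)."""
    means = [
        expected_item_mean(category_probabilities(meas, factor, j))
        for j in range(meas.n_items)
    ]
    return float(np.mean(means))


def population_observed_mean_difference(condition: PopulationCondition) -> float:
    """Focal minus reference population scale-score mean, each group under
    its own measurement parameters."""
    return expected_scale_score(condition.focal, condition.focal_factor) - expected_scale_score(
        condition.reference, condition.reference_factor
    )


def observed_mean_bias(condition: PopulationCondition) -> float:
    """Observed-mean bias induced by unique-factor noninvariance.

    Difference between the population observed mean difference of the
    condition and of its strict-invariant counterpart (focal unique
    variances reset to the reference values).  Zero whenever the condition
    is fully invariant, and exactly zero for items whose category
    distribution is symmetric in both groups.
    """
    return population_observed_mean_difference(condition) - population_observed_mean_difference(
        condition.invariant_counterpart()
    )
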