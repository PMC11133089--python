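"""Two-group ordinal response simulator under the probit item factor model."""

from __future__ import annotations

import zlib

import numpy as np

from .datasets import FOCAL, REFERENCE, OrdinalDataset
from .params import FactorParams, GroupMeasurementParams, PopulationCondition

__all__ = ["simulate_dataset", "dichotomize", "replication_seed"]


def _simulate_group(
    meas: GroupMeasurementParams,
    factor: FactorParams,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    eta = rng.normal(factor.mean, np.sqrt(factor.variance), size=n)
    eps = rng.normal(0.0, np.sqrt(meas.unique_variances), size=(n, meas.n_items))
    ystar = meas.intercepts + meas.loadings * eta[:, None] + eps
    # thresholds -> category index: count thresholds below the latent response
    y = np.zeros_like(ystar, dtype=np.int64)
    for c in range(meas.thresholds.shape[1]):
        y += ystar > meas.thresholds[:, c]
    return y


def simulate_dataset(condition: PopulationCondition, seed) -> OrdinalDataset:
    """Draw one two-group dataset from a population condition.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; the same
    seed reproduces the same matrix bit for bit.
    """
    rng = np.random.default_rng(seed)
    n = condition.group_size
    y_ref = _simulate_group(condition.reference, condition.reference_factor, n, rng)
    y_foc = _simulate_group(condition.focal, condition.focal_factor, n, rng)
    return OrdinalDataset(
        responses=np.vstack([y_ref, y_foc]),
        group_labels=np.array([REFERENCE] * n + [FOCAL] * n),
        n_categories=condition.n_categories,
    )


def dichotomize(data: OrdinalDataset, cut: int, original_base: int = 0) -> OrdinalDataset:
    """Collapse ordered categories into a binary item.

    ``cut`` refers to the *original published coding* with first category
    ``original_base`` (e.g. a 1-5 Likert item collapsed at 3 maps {1, 2} to
    0 and {3, 4, 5} to 1).  Internally categories are 0-based, so the rule
    applied is ``internal category >= cut - original_base``.
    """
    internal_cut = cut - original_base
    if not 1 <= internal_cut <= data.n_categories - 1:
        raise ValueError(
            f"cut={cut} outside the valid range for {data.n_categories} categories"
        )
    return OrdinalDataset(
        responses=(data.responses >= internal_cut).astype(np.int64),
        group_labels=data.group_labels,
        n_categories=2,
        item_names=data.item_names,
    )


def replication_seed(base_seed: int, condition_key: str, replication: int) -> np.random.SeedSequence:
    """Deterministic per-replication seed stream.

    One base seed governs a whole study; replication ``r`` of a condition
    draws from a stream derived from (base seed, condition key, r) so that
    conditions can be rerun or parallelized independently without overlap.
    """
    key = zlib.crc32(condition_key.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, key, int(replication)])
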