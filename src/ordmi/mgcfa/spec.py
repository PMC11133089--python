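"""Constraint systems for multigroup one-factor ordinal CFA.

A :class:`ModelSpec` records, for every model parameter (loading lambda_jk,
threshold tau_jk^(c), unique variance theta_jk, factor mean alpha_k, factor
variance psi_k), whether it is fixed, free, or equated to another
parameter, under the theta parameterization with latent intercepts nu fixed
to 0 in all groups.

Two identification styles are provided:

``liu``
    marker-variable identification used by the sequential testing
    pipeline: the marker item's loading is equated across groups, one
    threshold per item is equated (plus a second threshold of the marker
    for polytomous items), the reference group has alpha=0, psi=1 and all
    unique variances fixed to 1, and focal unique variances are free from
    the configural stage on.

``lavaan``
    the default multigroup identification of mainstream SEM software:
    thresholds and loadings free per group at the configural/metric stages
    with all unique variances fixed to 1, and — once loadings and
    thresholds are equated (scalar stage) — free focal unique variances,
    factor mean, and factor variance.

For dichotomous items the metric model is an equivalent reparameterization
of the configural model, so stage ``metric`` returns the configural spec
with a warning and testing proceeds configural -> scalar -> strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelSpec", "build_model_spec", "build_pooled_spec", "count_df"]

_STAGES = ("configural", "metric", "scalar", "strict")
_STYLES = ("liu", "lavaan")


@dataclass
class ModelSpec:
    stage: str
    n_items: int
    n_categories: int
    group_names: tuple
    id_style: str
    marker: int | None
    released: tuple
    lam_map: np.ndarray = field(repr=False, default=None)
    tau_map: np.ndarray = field(repr=False, default=None)
    theta_map: np.ndarray = field(repr=False, default=None)
    alpha_map: np.ndarray = field(repr=False, default=None)
    psi_map: np.ndarray = field(repr=False, default=None)
    lam_fix: np.ndarray = field(repr=False, default=None)
    tau_fix: np.ndarray = field(repr=False, default=None)
    theta_fix: np.ndarray = field(repr=False, default=None)
    alpha_fix: np.ndarray = field(repr=False, default=None)
    psi_fix: np.ndarray = field(repr=False, default=None)
    param_names: list = field(repr=False, default_factory=list)
    release_indices: dict = field(repr=False, default_factory=dict)
    _n_free_override: int | None = field(repr=False, default=None)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_free(self) -> int:
        if self._n_free_override is not None:
            return self._n_free_override
        return len(self.param_names)

    @property
    def n_moments(self) -> int:
        p, c = self.n_items, self.n_categories
        return self.n_groups * (p * (c - 1) + p * (p - 1) // 2)

    @property
    def fittable(self) -> bool:
        return self.lam_map is not None

    @classmethod
    def saturated(cls, n_items, n_categories, n_groups=2):
        """Bookkeeping-only spec with as many free parameters as moments."""
        spec = cls(
            stage="saturated",
            n_items=n_items,
            n_categories=n_categories,
            group_names=tuple(f"g{k}" for k in range(n_groups)),
            id_style="lavaan",
            marker=None,
            released=(),
        )
        spec._n_free_override = spec.n_moments
        return spec

    # -- parameter assembly ------------------------------------------------

    def assemble(self, x: np.ndarray) -> dict:
        """Expand a free-parameter vector into full per-group arrays."""
        x = np.asarray(x, float)

        def fill(mp, fx):
            out = fx.copy()
            m = mp >= 0
            out[m] = x[mp[m]]
            return out

        return {
            "lam": fill(self.lam_map, self.lam_fix),
            "tau": fill(self.tau_map, self.tau_fix),
            "theta": fill(self.theta_map, self.theta_fix),
            "alpha": fill(self.alpha_map, self.alpha_fix),
            "psi": fill(self.psi_map, self.psi_fix),
        }

    def slots(self):
        """Iterate (kind, group, item, cat, map_index, fixed_value)."""
        K, p, cm1 = self.n_groups, self.n_items, self.n_categories - 1
        for k in range(K):
            for j in range(p):
                yield ("lambda", k, j, None, self.lam_map[k, j], self.lam_fix[k, j])
                yield ("theta", k, j, None, self.theta_map[k, j], self.theta_fix[k, j])
                for c in range(cm1):
                    yield ("tau", k, j, c, self.tau_map[k, j, c], self.tau_fix[k, j, c])
            yield ("alpha", k, None, None, self.alpha_map[k], self.alpha_fix[k])
            yield ("psi", k, None, None, self.psi_map[k], self.psi_fix[k])

    def free_index(self, kind, group, item=None, cat=None) -> int:
        mp = {
            "lambda": self.lam_map,
            "tau": self.tau_map,
            "theta": self.theta_map,
            "alpha": self.alpha_map,
            "psi": self.psi_map,
        }[kind]
        idx = (
            mp[group]
            if item is None
            else (mp[group, item] if cat is None else mp[group, item, cat])
        )
        if idx < 0:
            raise ValueError(f"{kind} is fixed in this spec")
        return int(idx)

    def releasable_constraints(self) -> list:
        """Cross-group equality constraints that a partial-invariance search
        may free at this spec's stage."""
        out = []
        p, cm1 = self.n_items, self.n_categories - 1
        released = set(self.released)
        if self.stage == "metric":
            for j in range(p):
                if j == self.marker or ("lambda", j) in released:
                    continue
                if self.lam_map[0, j] == self.lam_map[1, j]:
                    out.append(("lambda", j))
        elif self.stage == "scalar":
            if self.n_categories == 2:
                # thresholds already anchor identification; the scalar
                # stage's new constraints for dichotomous items are loadings
                for j in range(p):
                    if j == self.marker or ("lambda", j) in released:
                        continue
                    if self.lam_map[0, j] == self.lam_map[1, j]:
                        out.append(("lambda", j))
            else:
                for j in range(p):
                    for c in range(cm1):
                        if ("tau", j, c) in released:
                            continue
                        if self.id_style == "liu" and j == self.marker and c in (0, 1):
                            continue
                        if self.tau_map[0, j, c] == self.tau_map[1, j, c]:
                            out.append(("tau", j, c))
        elif self.stage == "strict":
            for j in range(p):
                if ("theta", j) in released:
                    continue
                if self.theta_map[1, j] < 0:  # fixed to the reference value
                    out.append(("theta", j))
        return out

    def with_release(self, token) -> "ModelSpec":
        return build_model_spec(
            self.stage,
            self.n_items,
            self.n_categories,
            marker=self.marker,
            released=tuple(self.released) + (tuple(token),),
            id_style=self.id_style,
            group_names=self.group_names,
        )


def count_df(spec: ModelSpec) -> int:
    """Model degrees of freedom: sample moments minus free parameters."""
    return spec.n_moments - spec.n_free


def _validate_releases(released, marker, n_items, n_categories, id_style, stage):
    for token in released:
        kind = token[0]
        if kind == "lambda":
            j = token[1]
            if id_style == "liu" and j == marker:
                raise ValueError("cannot release the marker loading; re-select the marker")
        elif kind == "tau":
            j, c = token[1], token[2]
            if not (0 <= c <= n_categories - 2):
                raise ValueError(f"threshold index {c} out of range")
            if id_style == "liu" and j == marker and c in (0, 1):
                raise ValueError(
                    "cannot release the marker's identification thresholds; re-select the marker"
                )
        elif kind == "theta":
            if stage not in ("strict",):
                raise ValueError("unique variances are only constrained in the strict stage")
        else:
            raise ValueError(f"unknown constraint token {token!r}")
        if not (0 <= token[1] < n_items):
            raise ValueError(f"item index {token[1]} out of range")


def build_model_spec(
    stage: str,
    n_items: int,
    n_categories: int,
    marker: int | None = None,
    released=(),
    id_style: str = "lavaan",
    group_names=("reference", "focal"),
) -> ModelSpec:
    """Construct the free/fixed/equality pattern of an invariance stage.

    ``released`` lists constraints freed from the stage's cross-group
    equalities (partial invariance): ``("lambda", j)``, ``("tau", j, c)``
    or ``("theta", j)``.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; valid: {_STAGES}")
    if id_style not in _STYLES:
        raise ValueError(f"unknown id_style {id_style!r}; valid: {_STYLES}")
    if len(group_names) != 2:
        raise ValueError("two groups are required (reference first)")
    p, C = int(n_items), int(n_categories)
    if id_style == "liu":
        if marker is None:
            raise ValueError("liu identification requires a marker item")
        if not 0 <= marker < p:
            raise ValueError("marker index out of range")
    released = tuple(tuple(t) for t in released)
    _validate_releases(released, marker, p, C, id_style, stage)

    if stage == "metric" and C == 2:
        warnings.warn(
            "the metric model is equivalent to the configural model for "
            "dichotomous items; returning the configural spec",
            stacklevel=2,
        )
        return build_model_spec(
            "configural", p, C, marker=marker, released=released,
            id_style=id_style, group_names=group_names,
        )

    rel_lam = {t[1] for t in released if t[0] == "lambda"}
    rel_tau = {(t[1], t[2]) for t in released if t[0] == "tau"}
    rel_theta = {t[1] for t in released if t[0] == "theta"}

    names: list = []

    def new(name):
        names.append(name)
        return len(names) - 1

    lam_map = np.full((2, p), -1, dtype=int)
    tau_map = np.full((2, p, C - 1), -1, dtype=int)
    theta_map = np.full((2, p), -1, dtype=int)
    alpha_map = np.full(2, -1, dtype=int)
    psi_map = np.full(2, -1, dtype=int)
    lam_fix = np.zeros((2, p))
    tau_fix = np.zeros((2, p, C - 1))
    theta_fix = np.ones((2, p))
    alpha_fix = np.zeros(2)
    psi_fix = np.ones(2)
    release_indices: dict = {}

    equal_loadings = stage in ("metric", "scalar", "strict")
    equal_thresholds = stage in ("scalar", "strict")
    configural_like = stage in ("configural", "metric")

    # loadings
    for j in range(p):
        shared = new(f"lambda[{j}]")
        lam_map[0, j] = shared
        if equal_loadings:
            if j in rel_lam:
                idx = new(f"lambda[{j}].focal")
                lam_map[1, j] = idx
                release_indices[("lambda", j)] = idx
            else:
                lam_map[1, j] = shared
        else:  # configural
            if id_style == "liu" and j == marker:
                lam_map[1, j] = shared
            else:
                lam_map[1, j] = new(f"lambda[{j}].focal")

    # thresholds
    for j in range(p):
        for c in range(C - 1):
            shared = new(f"tau[{j},{c}]")
            tau_map[0, j, c] = shared
            if equal_thresholds:
                if (j, c) in rel_tau:
                    idx = new(f"tau[{j},{c}].focal")
                    tau_map[1, j, c] = idx
                    release_indices[("tau", j, c)] = idx
                else:
                    tau_map[1, j, c] = shared
            else:
                anchor = c == 0 or (j == marker and c == 1 and C > 2)
                if id_style == "liu" and anchor:
                    tau_map[1, j, c] = shared
                else:
                    tau_map[1, j, c] = new(f"tau[{j},{c}].focal")

    # unique variances: reference fixed to 1 throughout (theta param.)
    for j in range(p):
        focal_free = (
            stage == "scalar"
            or (stage == "strict" and j in rel_theta)
            or (configural_like and id_style == "liu")
        )
        if focal_free:
            idx = new(f"theta[{j}].focal")
            theta_map[1, j] = idx
            if stage == "strict" and j in rel_theta:
                release_indices[("theta", j)] = idx

    # factor mean and variance
    if stage in ("scalar", "strict") or (configural_like and id_style == "liu"):
        alpha_map[1] = new("alpha.focal")
        # dichotomous items provide no second marker threshold, so the
        # focal factor variance is not identified until loadings are
        # equated; keep it fixed at 1 in the liu configural model
        if not (configural_like and id_style == "liu" and C == 2):
            psi_map[1] = new("psi.focal")
    elif stage == "metric":  # lavaan style: variance identified, mean not
        psi_map[1] = new("psi.focal")

    return ModelSpec(
        stage=stage,
        n_items=p,
        n_categories=C,
        group_names=tuple(group_names),
        id_style=id_style,
        marker=marker,
        released=released,
        lam_map=lam_map,
        tau_map=tau_map,
        theta_map=theta_map,
        alpha_map=alpha_map,
        psi_map=psi_map,
        lam_fix=lam_fix,
        tau_fix=tau_fix,
        theta_fix=theta_fix,
        alpha_fix=alpha_fix,
        psi_fix=psi_fix,
        param_names=names,
        release_indices=release_indices,
    )


def build_pooled_spec(n_items: int, n_categories: int) -> ModelSpec:
    """Single-group one-factor spec (free loadings and thresholds, theta=1,
    alpha=0, psi=1); used for marker selection on pooled data."""
    p, C = int(n_items), int(n_categories)
    names: list = []

    def new(name):
        names.append(name)
        return len(names) - 1

    lam_map = np.array([[new(f"lambda[{j}]") for j in range(p)]])
    tau_map = np.array(
        [[[new(f"tau[{j},{c}]") for c in range(C - 1)] for j in range(p)]]
    )
    return ModelSpec(
        stage="pooled",
        n_items=p,
        n_categories=C,
        group_names=("pooled",),
        id_style="lavaan",
        marker=None,
        released=(),
        lam_map=lam_map,
        tau_map=tau_map,
        theta_map=np.full((1, p), -1, dtype=int),
        alpha_map=np.full(1, -1, dtype=int),
        psi_map=np.full(1, -1, dtype=int),
        lam_fix=np.zeros((1, p)),
        tau_fix=np.zeros((1, p, C - 1)),
        theta_fix=np.ones((1, p)),
        alpha_fix=np.zeros(1),
        psi_fix=np.ones(1),
        param_names=names,
    )
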