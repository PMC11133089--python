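"""Sequential measurement-invariance testing with partial-invariance search.

The pipeline mirrors accepted practice for ordered-categorical items:
select a marker item from a pooled one-factor fit, test configural ->
metric -> scalar -> strict invariance with scaled chi-square difference
tests (metric is skipped for dichotomous items, where it is equivalent to
configural), and on rejection run a modification-index-guided sequential
search that frees one constraint at a time until the partial model is no
longer significantly worse than the previously accepted stage.  The final
report states which mean comparisons the attained invariance level
supports: observed means require full strict invariance; factor means are
valid under (partial) scalar invariance for polytomous items but require
(partial) strict invariance for dichotomous items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import OrdinalDataset
from .mgcfa import build_model_spec, fit, modification_indices, scaled_difference_test
from .mgcfa.fit import FitOptions, FitResult
from .mgcfa.inference import DifferenceTest
from .mgcfa.spec import build_pooled_spec
from .polychoric import PolychoricSummary, summary_statistics

__all__ = [
    "select_marker",
    "run_sequence",
    "partial_search",
    "StageReport",
    "StageRecord",
    "mean_comparison_validity",
]


def select_marker(data: OrdinalDataset, summary: PolychoricSummary | None = None) -> int:
    """Index of the item with the largest loading in a pooled one-factor fit.

    Ties break to the lowest index.  The pipeline re-selects downstream if
    the marker turns out noninvariant.
    """
    if data.n_items < 2:
        raise ValueError("marker selection requires at least two items")
    if summary is None:
        summary = summary_statistics(data, pooled=True)
    order = marker_candidates(data, summary)
    return order[0]


def marker_candidates(data: OrdinalDataset, pooled_summary: PolychoricSummary) -> list:
    """Items ranked by pooled-fit loading, best first."""
    spec = build_pooled_spec(data.n_items, data.n_categories)
    res = fit(pooled_summary, spec)
    lams = np.array(
        [res.estimates[spec.lam_map[0, j]] for j in range(data.n_items)]
    )
    # stable sort: ties go to the lowest index
    return list(np.argsort(-lams, kind="stable"))


def mean_comparison_validity(item_type: str, attained_stage: str, partial: bool) -> dict:
    """Which mean comparisons an attained invariance level supports.

    ``item_type`` is "dichotomous" or "polytomous"; ``attained_stage`` the
    final accepted model stage; ``partial`` whether any constraint was
    released in the final model.
    """
    if item_type not in ("dichotomous", "polytomous"):
        raise ValueError("item_type must be 'dichotomous' or 'polytomous'")
    order = {"configural": 0, "metric": 1, "scalar": 2, "strict": 3}
    level = order[attained_stage]
    observed = attained_stage == "strict" and not partial
    if item_type == "polytomous":
        factor = level >= order["scalar"]
    else:
        factor = level >= order["strict"]
    return {"observed_mean_valid": observed, "factor_mean_valid": factor}


@dataclass
class StageRecord:
    stage: str
    result: FitResult
    difference_vs_previous: DifferenceTest | None
    released: tuple
    note: str = ""


@dataclass
class StageReport:
    records: list
    marker: int
    item_type: str
    attained_stage: str
    partial: bool
    released: tuple
    item_levels: dict
    verdict: dict
    audit: list = field(default_factory=list)

    @property
    def final(self) -> FitResult:
        return self.records[-1].result

    def to_dict(self) -> dict:
        return {
            "marker": int(self.marker),
            "item_type": self.item_type,
            "attained_stage": self.attained_stage,
            "partial": bool(self.partial),
            "released": [list(t) for t in self.released],
            "item_levels": {int(k): v for k, v in self.item_levels.items()},
            "verdict": self.verdict,
            "audit": list(self.audit),
            "stages": [
                {
                    "stage": r.stage,
                    "df": int(r.result.df),
                    "stat_scaled": float(r.result.stat_scaled),
                    "converged": bool(r.result.converged),
                    "diff_p": (
                        float(r.difference_vs_previous.p_value)
                        if r.difference_vs_previous is not None
                        else None
                    ),
                    "released": [list(t) for t in r.released],
                    "note": r.note,
                }
                for r in self.records
            ],
        }


class SearchExhausted(RuntimeError):
    """Partial-invariance search freed every releasable constraint without
    reaching an acceptable model (full noninvariance at this stage)."""


def partial_search(
    rejected: FitResult,
    parent: FitResult,
    summary: PolychoricSummary,
    accept_alpha: float = 0.01,
    options: FitOptions | None = None,
    audit: list | None = None,
):
    """Free constraints one at a time, largest modification index first.

    Stops as soon as the scaled difference test against ``parent`` is
    nonsignificant at ``accept_alpha``; marker identification constraints
    are never candidates.  Returns the accepted partial fit and the trail
    of released constraints; raises :class:`SearchExhausted` when every
    candidate has been freed without acceptance.
    """
    current = rejected
    trail = []
    while True:
        if not current.converged:
            raise SearchExhausted("partial search hit a nonconverged fit")
        mis = modification_indices(current)
        if mis.empty:
            raise SearchExhausted("no releasable constraint remains")
        best = mis.loc[mis["mi"].idxmax()]
        token = tuple(best["constraint"])
        new_spec = current.spec.with_release(token)
        candidate = fit(summary, new_spec, options)
        trail.append(token)
        if audit is not None:
            audit.append(
                f"released {token} (MI={best['mi']:.2f}) at stage {current.spec.stage}"
            )
        if not candidate.converged:
            current = candidate
            continue
        diff = scaled_difference_test(candidate, parent)
        if diff.p_value > accept_alpha:
            return candidate, tuple(trail), diff
        current = candidate


def run_sequence(
    data: OrdinalDataset,
    alpha: float = 0.05,
    id_style: str = "liu",
    accept_alpha: float = 0.01,
    options: FitOptions | None = None,
) -> StageReport:
    """Run the full sequential invariance-testing procedure on a two-group
    ordinal dataset and report the attained level and mean-comparison
    verdict."""
    summary = summary_statistics(data)
    pooled = summary_statistics(data, pooled=True)
    candidates = (
        marker_candidates(data, pooled) if id_style == "liu" else [None]
    )
    last_error = None
    for marker in candidates:
        try:
            return _run_with_marker(
                data, summary, marker, alpha, id_style, accept_alpha, options
            )
        except SearchExhausted as err:
            last_error = err
            continue
    raise RuntimeError(
        "no admissible marker/model sequence found; all candidate markers "
        f"exhausted ({last_error}); review partial invariance manually"
    )


def _strict_released(scalar_released, n_items):
    """Unique variances stay free for items whose thresholds or loading
    were freed (their metric is not comparable)."""
    items = {t[1] for t in scalar_released}
    return tuple(("theta", j) for j in sorted(items))


def _run_with_marker(data, summary, marker, alpha, id_style, accept_alpha, options):
    p, C = data.n_items, data.n_categories
    dichotomous = C == 2
    stages = ["configural", "scalar", "strict"] if dichotomous else [
        "configural",
        "metric",
        "scalar",
        "strict",
    ]
    records = []
    audit = []
    released: tuple = ()
    previous = None
    attained = "configural"
    partial_flag = False
    for stage in stages:
        stage_released = released
        if stage == "strict":
            stage_released = released + _strict_released(released, p)
        spec = build_model_spec(
            stage, p, C, marker=marker, released=stage_released, id_style=id_style
        )
        result = fit(summary, spec, options)
        if stage == "configural":
            if not result.converged:
                raise RuntimeError(
                    f"configural model did not converge ({result.message}); "
                    "cannot proceed with invariance testing"
                )
            records.append(StageRecord(stage, result, None, ()))
            previous = result
            continue
        if not result.converged:
            # an empirically underidentified intermediate stage (common for
            # the dichotomous scalar model) is recorded and skipped; the
            # next stage is tested against the last accepted model
            audit.append(f"stage {stage}: nonconverged; skipped")
            records.append(StageRecord(stage, result, None, (), note="nonconverged"))
            continue
        diff = scaled_difference_test(result, previous)
        if diff.p_value > alpha:
            records.append(StageRecord(stage, result, diff, ()))
            previous = result
            attained = stage
            released = stage_released
            continue
        # rejected: search for a partial model
        audit.append(f"stage {stage}: difference test rejected; starting partial search")
        partial_fit, trail, pdiff = partial_search(
            result, previous, summary, accept_alpha, options, audit
        )
        records.append(StageRecord(stage, partial_fit, pdiff, trail, note="partial"))
        previous = partial_fit
        attained = stage
        partial_flag = True
        released = tuple(partial_fit.spec.released)

    item_levels = _item_levels(p, attained, released)
    verdict = mean_comparison_validity(
        "dichotomous" if dichotomous else "polytomous", attained, partial_flag
    )
    return StageReport(
        records=records,
        marker=-1 if marker is None else marker,
        item_type="dichotomous" if dichotomous else "polytomous",
        attained_stage=attained,
        partial=partial_flag,
        released=released,
        item_levels=item_levels,
        verdict=verdict,
        audit=audit,
    )


def _item_levels(p, attained, released):
    """Final attained invariance level per item given released constraints."""
    levels = {}
    rel_lam = {t[1] for t in released if t[0] == "lambda"}
    rel_tau = {t[1] for t in released if t[0] == "tau"}
    rel_theta = {t[1] for t in released if t[0] == "theta"}
    for j in range(p):
        if j in rel_lam:
            levels[j] = "configural"
        elif j in rel_tau:
            levels[j] = "metric"
        elif j in rel_theta:
            levels[j] = "scalar"
        else:
            levels[j] = attained
    return levels
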