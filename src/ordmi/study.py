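"""Monte Carlo harness for observed-mean and factor-mean comparisons.

Per replication the harness simulates a two-group dataset from a
population condition and runs up to three analyses: an independent-samples
t-test on person-level scale scores (mean of item scores), a Wald test of
the focal factor mean in the scalar invariance model, and the same test in
the correctly specified strict (or partial strict) model that equates
unique variances except for the truly noninvariant items.  Summaries
report rejection rates (among converged fits for the model-based
analyses), raw bias against the population mean difference, empirical
standard errors, and convergence rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import OrdinalDataset
from .mgcfa import build_model_spec, fit, wald_factor_mean
from .mgcfa.fit import FitOptions
from .moments import population_observed_mean_difference
from .params import PopulationCondition
from .polychoric import EmptyCategoryError, summary_statistics
from .simulate import replication_seed, simulate_dataset

__all__ = [
    "observed_mean_ttest",
    "TTestResult",
    "run_condition",
    "run_grid",
    "acceptable_range",
    "ConditionSummary",
    "condition_key",
]

ANALYSES = ("ttest", "scalar_wald", "strict_wald")


@dataclass
class TTestResult:
    statistic: float
    df: int
    p_value: float
    mean_difference: float


def observed_mean_ttest(data: OrdinalDataset) -> TTestResult:
    """Pooled-variance two-sample t-test on per-person scale scores.

    The scale score is the mean of the item scores; the difference is
    focal minus reference (second group minus first).
    """
    groups = data.groups
    if len(groups) != 2:
        raise ValueError("the t-test requires exactly two groups")
    ref = data.group(groups[0]).mean(axis=1)
    foc = data.group(groups[1]).mean(axis=1)
    n_r, n_f = ref.size, foc.size
    if n_r < 2 or n_f < 2:
        raise ValueError("both groups need at least two observations")
    ss = ((ref - ref.mean()) ** 2).sum() + ((foc - foc.mean()) ** 2).sum()
    df = n_r + n_f - 2
    pooled = ss / df
    if pooled <= 0:
        raise ValueError("zero pooled variance; t-test undefined")
    diff = foc.mean() - ref.mean()
    se = np.sqrt(pooled * (1.0 / n_r + 1.0 / n_f))
    t = diff / se
    return TTestResult(
        statistic=float(t),
        df=int(df),
        p_value=float(2.0 * stats.t.sf(abs(t), df)),
        mean_difference=float(diff),
    )


@dataclass
class ConditionSummary:
    """Aggregated Monte Carlo results for one condition and analysis."""

    condition: str
    analysis: str
    n_reps: int
    rejection_rate: float
    raw_bias: float
    empirical_se: float
    convergence_rate: float
    seed: int

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "analysis": self.analysis,
            "n_reps": self.n_reps,
            "rejection_rate": self.rejection_rate,
            "raw_bias": self.raw_bias,
            "empirical_se": self.empirical_se,
            "convergence_rate": self.convergence_rate,
            "seed": self.seed,
        }


def condition_key(condition: PopulationCondition) -> str:
    c = condition
    return (
        f"{c.parameter_set}/C{c.n_categories}/n{c.group_size}/"
        f"p{c.n_noninvariant}/d{c.noninvariance_factor:g}/a{c.focal_factor_mean:g}"
    )


def _scalar_spec(condition: PopulationCondition):
    return build_model_spec(
        "scalar", condition.reference.n_items, condition.n_categories, id_style="lavaan"
    )


def _strict_spec(condition: PopulationCondition):
    """Correctly specified strict (or partial strict) spec: unique-variance
    equality released exactly for the truly noninvariant items."""
    released = tuple(("theta", int(j)) for j in condition.noninvariant_items)
    return build_model_spec(
        "strict",
        condition.reference.n_items,
        condition.n_categories,
        released=released,
        id_style="lavaan",
    )


def run_condition(
    condition: PopulationCondition,
    n_reps: int,
    seed: int,
    analyses=ANALYSES,
    alpha: float = 0.05,
    options: FitOptions | None = None,
) -> list:
    """Monte Carlo replications of one condition.

    Returns one :class:`ConditionSummary` per requested analysis.
    Model-based rejection rates and biases are computed among converged
    replications; empty-category replications count as nonconverged for the
    models but still feed the t-test.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    key = condition_key(condition)
    do_models = any(a in analyses for a in ("scalar_wald", "strict_wald"))
    specs = {}
    if "scalar_wald" in analyses:
        specs["scalar_wald"] = _scalar_spec(condition)
    if "strict_wald" in analyses:
        specs["strict_wald"] = _strict_spec(condition)

    t_reject, t_diffs = [], []
    model_rej = {a: [] for a in specs}
    model_est = {a: [] for a in specs}
    model_conv = {a: [] for a in specs}

    for r in range(n_reps):
        data = simulate_dataset(condition, replication_seed(seed, key, r))
        if "ttest" in analyses:
            tt = observed_mean_ttest(data)
            t_reject.append(tt.p_value < alpha)
            t_diffs.append(tt.mean_difference)
        if do_models:
            try:
                summary = summary_statistics(data)
            except EmptyCategoryError:
                for a in specs:
                    model_conv[a].append(False)
                continue
            for a, spec in specs.items():
                res = fit(summary, spec, options)
                model_conv[a].append(res.converged)
                if res.converged:
                    wr = wald_factor_mean(res)
                    model_rej[a].append(wr.p_value < alpha)
                    model_est[a].append(wr.estimate)

    out = []
    benchmark = population_observed_mean_difference(condition.invariant_counterpart())
    if "ttest" in analyses:
        out.append(
            ConditionSummary(
                condition=key,
                analysis="ttest",
                n_reps=n_reps,
                rejection_rate=100.0 * np.mean(t_reject),
                raw_bias=float(np.mean(t_diffs) - benchmark),
                empirical_se=float(np.std(t_diffs, ddof=1)) if len(t_diffs) > 1 else np.nan,
                convergence_rate=100.0,
                seed=seed,
            )
        )
    for a in specs:
        conv = np.asarray(model_conv[a], dtype=bool)
        est = np.asarray(model_est[a], dtype=float)
        out.append(
            ConditionSummary(
                condition=key,
                analysis=a,
                n_reps=n_reps,
                rejection_rate=100.0 * np.mean(model_rej[a]) if model_rej[a] else np.nan,
                raw_bias=(
                    float(est.mean() - condition.focal_factor_mean) if est.size else np.nan
                ),
                empirical_se=float(est.std(ddof=1)) if est.size > 1 else np.nan,
                convergence_rate=100.0 * conv.mean() if conv.size else np.nan,
                seed=seed,
            )
        )
    return out


def run_grid(
    conditions,
    n_reps: int,
    seed: int,
    analyses=ANALYSES,
    alpha: float = 0.05,
    n_jobs: int = 1,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Run a list of conditions and return a tidy summary table.

    Each condition draws from its own deterministic seed stream, so the
    result is identical whatever ``n_jobs`` is.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("empty condition grid")

    def one(cond):
        return run_condition(cond, n_reps, seed, analyses, alpha, options)

    if n_jobs == 1:
        batches = [one(c) for c in conditions]
    else:
        from joblib import Parallel, delayed

        batches = Parallel(n_jobs=n_jobs)(delayed(one)(c) for c in conditions)
    rows = [s.to_row() for batch in batches for s in batch]
    return pd.DataFrame(rows)


def acceptable_range(alpha: float, n_reps: int) -> tuple:
    """Two-standard-error band (in %) around the nominal rejection rate:
    100*(alpha +/- 2*sqrt(alpha*(1-alpha)/R))."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    se = np.sqrt(alpha * (1 - alpha) / n_reps)
    return (100.0 * (alpha - 2 * se), 100.0 * (alpha + 2 * se))
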