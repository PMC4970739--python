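"""Cost-effectiveness comparison, scenario runner, and tornado analysis.

This module assembles the full pipeline — pool curves per model branch, fit
and average the Weibull extrapolations, derive per-cycle transition
schedules, build the decision-tree strategies, run the semi-Markov cohort,
and discount costs and QALYs — and then compares strategies pairwise
(ICER / dominance), re-runs the pipeline under scenario overrides, and
performs one-way (tornado) sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Any, Callable, Mapping, Sequence

from .config import RunConfig
from .decision_tree import BranchProportions, branch_proportions
from .markov_engine import (CycleConfig, StrategyDefinition, TreatmentLine,
                            accumulate_costs, accumulate_qalys, run_cohort)
from .survival_models import (SurvivalCurve, TransitionSchedule,
                              average_models, fit_least_squares,
                              fit_regression, pool_curves, sse,
                              to_transition_schedule)

log = logging.getLogger(__name__)

__all__ = [
    "CEResult",
    "Comparison",
    "TornadoEntry",
    "PipelineResult",
    "compare",
    "tornado",
    "run_scenario",
    "evaluate",
    "build_strategy",
    "fit_branches",
    "SCENARIOS",
]


@dataclass(frozen=True)
class CEResult:
    """Discounted per-patient cost and effect of one strategy."""

    strategy: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.effect < 0:
            raise ValueError("cost and effect must be non-negative")


@dataclass(frozen=True)
class Comparison:
    """Pairwise incremental comparison (intervention minus comparator)."""

    intervention: str
    comparator: str
    incr_cost: float
    incr_effect: float
    icer: float | None
    verdict: str  # "dominant" | "dominated" | "undefined ICER" | "icer"


def compare(intervention: CEResult, comparator: CEResult) -> Comparison:
    """Incremental comparison with dominance labelling.

    The intervention is *dominant* when it is cheaper and more effective,
    *dominated* when costlier and less effective. The ICER is reported only
    when the incremental effect is non-zero; equal effects yield the
    explicit "undefined ICER" verdict rather than an exception.
    """
    d_cost = intervention.cost - comparator.cost
    d_eff = intervention.effect - comparator.effect
    if d_cost < 0 and d_eff > 0:
        return Comparison(intervention.strategy, comparator.strategy,
                          d_cost, d_eff, None, "dominant")
    if d_cost > 0 and d_eff < 0:
        return Comparison(intervention.strategy, comparator.strategy,
                          d_cost, d_eff, None, "dominated")
    if d_eff == 0:
        return Comparison(intervention.strategy, comparator.strategy,
                          d_cost, d_eff, None, "undefined ICER")
    return Comparison(intervention.strategy, comparator.strategy,
                      d_cost, d_eff, d_cost / d_eff, "icer")


# ---------------------------------------------------------------------------
# pipeline assembly


@dataclass
class BranchFit:
    branch: str
    pooled: SurvivalCurve
    regression: Any
    least_squares: Any
    chosen: Callable
    schedule: TransitionSchedule


@dataclass
class PipelineResult:
    config: RunConfig
    proportions: BranchProportions
    fits: dict[str, BranchFit]
    results: dict[str, CEResult]
    comparison: Comparison | None

    def fit_report_rows(self) -> list[dict]:
        rows = []
        for b in self.fits.values():
            for method, model in (("regression", b.regression),
                                  ("least_squares", b.least_squares)):
                rows.append({"branch": b.branch, "method": method,
                             "shape": model.shape, "scale": model.scale,
                             "sse": sse(model, b.pooled)})
        return rows


# fits depend only on (curves object, extrapolation, horizon); scenario and
# tornado runs re-enter with the same curves mapping, so memoize on identity
_FIT_CACHE: dict[tuple[int, str, int], tuple[Any, dict[str, "BranchFit"]]] = {}


def fit_branches(config: RunConfig,
                 curves: Mapping[str, Sequence[SurvivalCurve]]) -> dict[str, BranchFit]:
    """Pool, fit (both methods), select the configured extrapolation, and
    derive the per-cycle transition schedule for every curve branch.

    Results are memoized per (curves mapping, extrapolation, horizon); the
    curves mapping is treated as immutable once passed in.
    """
    key = (id(curves), config.extrapolation, config.cycle.horizon)
    hit = _FIT_CACHE.get(key)
    if hit is not None and hit[0] is curves:
        return hit[1]
    fits: dict[str, BranchFit] = {}
    for branch, curve_list in curves.items():
        pooled = pool_curves(list(curve_list), label=branch)
        reg = fit_regression(pooled)
        lsq = fit_least_squares(pooled)
        chosen: Callable
        if config.extrapolation == "regression":
            chosen = reg
        elif config.extrapolation == "least_squares":
            chosen = lsq
        else:
            chosen = average_models(lsq, reg)
        schedule = to_transition_schedule(chosen, config.cycle.horizon)
        fits[branch] = BranchFit(branch, pooled, reg, lsq, chosen, schedule)
    _FIT_CACHE[key] = (curves, fits)
    return fits


def _resolve_weight(weight: str | float, props: BranchProportions) -> float:
    if isinstance(weight, str):
        if weight == "all":
            return 1.0
        return getattr(props, weight)
    return float(weight)


def _build_line(config: RunConfig, binding, fits: Mapping[str, BranchFit],
                horizon: int) -> TreatmentLine:
    reg = config.regimens[binding.regimen]
    scale = config.cost_scale.get(binding.regimen, 1.0)
    adj = 0.0
    if reg.oral:
        adj += config.utilities["oral_adjustment"]
    elif config.iv_disutility_scenario and binding.regimen != "BSC":
        adj -= config.utilities["iv_disutility"]
    admin_cycles = reg.admin_cycle_count(horizon)
    ae_cycles = admin_cycles if config.ae_whole_admin_period else 1
    return TreatmentLine(
        label=binding.regimen,
        os_schedule=fits[binding.os].schedule,
        pfs_schedule=None if binding.pfs is None else fits[binding.pfs].schedule,
        cost_admin_per_cycle=reg.cost_admin * scale,
        cost_nonadmin_per_cycle=reg.cost_nonadmin * scale,
        admin_cycles=admin_cycles,
        utility=config.utilities[binding.utility],
        utility_adjustment=adj,
        ae_disutility_total=reg.ae_disutility,
        ae_cycles=ae_cycles,
        is_oral=reg.oral,
    )


def build_strategy(config: RunConfig, name: str, fits: Mapping[str, BranchFit],
                   props: BranchProportions) -> StrategyDefinition:
    spec = config.strategies[name]
    arms = []
    for arm in spec.arms:
        weight = _resolve_weight(arm.weight, props)
        path = tuple(_build_line(config, b, fits, config.cycle.horizon)
                     for b in arm.lines)
        arms.append((weight, path))
    test_cost = 0.0
    if spec.test_cost_applies:
        test_cost = config.test_cost * config.cost_scale.get("test", 1.0)
    return StrategyDefinition(name, arms, test_cost=test_cost)


def evaluate(config: RunConfig,
             curves: Mapping[str, Sequence[SurvivalCurve]],
             intervention: str = "testing",
             comparator: str = "no_testing") -> PipelineResult:
    """Run the full pipeline for every strategy in the configuration."""
    fits = fit_branches(config, curves)
    props = branch_proportions(config.prevalence, config.test)
    results: dict[str, CEResult] = {}
    for name in config.strategies:
        strategy = build_strategy(config, name, fits, props)
        trace = run_cohort(strategy, config.cycle)
        results[name] = CEResult(
            name,
            cost=accumulate_costs(trace, strategy, config.cycle),
            effect=accumulate_qalys(trace, strategy, config.cycle),
        )
    comparison = None
    if intervention in results and comparator in results:
        comparison = compare(results[intervention], results[comparator])
    return PipelineResult(config, props, fits, results, comparison)


# ---------------------------------------------------------------------------
# scenarios

#: Scenario registry mirroring the published sensitivity analyses: the two
#: single-method extrapolations, the alternative OS substitution for
#: first-line targeted therapy, the two alternative chemotherapy-regimen
#: models, and the two utility variants.
SCENARIOS: dict[str, dict[str, Any]] = {
    "extrapolation_regression": {"extrapolation": "regression"},
    "extrapolation_least_squares": {"extrapolation": "least_squares"},
    "os_substitution_cpem": {
        "strategies.testing.arms.0.lines.0.os": "os_cpem1_all",
    },
    "ert_pem": {
        "strategies.testing.arms.0.lines.1.regimen": "PEM",
        "strategies.testing.arms.0.lines.1.pfs": "pfs_pem2_all",
        "strategies.testing.arms.0.lines.1.os": "os_pem2_all",
    },
    "cgem_pem": {
        "strategies.testing.arms.1.lines.0.regimen": "CGEM",
        "strategies.testing.arms.1.lines.0.pfs": "pfs_cgem1_all",
        "strategies.testing.arms.1.lines.0.os": "os_cgem1_all",
        "strategies.testing.arms.1.lines.1.regimen": "PEM",
        "strategies.testing.arms.1.lines.1.pfs": "pfs_pem2_all",
        "strategies.testing.arms.1.lines.1.os": "os_pem2_all",
        "strategies.no_testing.arms.0.lines.0.regimen": "CGEM",
        "strategies.no_testing.arms.0.lines.0.pfs": "pfs_cgem1_all",
        "strategies.no_testing.arms.0.lines.0.os": "os_cgem1_all",
    },
    "ae_whole_admin_period": {"ae_whole_admin_period": True},
    "iv_disutility": {"iv_disutility_scenario": True},
}


def run_scenario(base_config: RunConfig,
                 overrides: Mapping[str, Any],
                 curves: Mapping[str, Sequence[SurvivalCurve]],
                 **kwargs) -> PipelineResult:
    """Re-run the full pipeline under dotted-path configuration overrides.

    ``overrides`` may also be the name of a registered scenario.
    """
    if isinstance(overrides, str):
        if overrides not in SCENARIOS:
            raise KeyError(
                f"unknown scenario {overrides!r}; valid: {sorted(SCENARIOS)}")
        overrides = SCENARIOS[overrides]
    cfg = base_config.with_overrides(overrides) if overrides else base_config
    return evaluate(cfg, curves, **kwargs)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    value_low: float | None
    value_high: float | None
    error: str | None = None

    @property
    def width(self) -> float:
        if self.value_low is None or self.value_high is None:
            return 0.0
        return abs(self.value_high - self.value_low)


def tornado(model: Callable[[str, float], float],
            params: Sequence[tuple[str, float, float]]) -> list[TornadoEntry]:
    """One-way sensitivity analysis.

    ``model(name, value)`` returns the summary statistic with the single
    named parameter set to ``value``. A model failure at an endpoint flags
    the entry and the analysis continues. Entries are sorted by descending
    bar width.
    """
    entries = []
    for name, low, high in params:
        try:
            v_low = float(model(name, low))
            v_high = float(model(name, high))
            entries.append(TornadoEntry(name, low, high, v_low, v_high))
        except Exception as e:  # noqa: BLE001 - continue past bad endpoints
            log.warning("tornado endpoint failed for %s: %s", name, e)
            entries.append(TornadoEntry(name, low, high, None, None, error=str(e)))
    return sorted(entries, key=lambda e: e.width, reverse=True)


def default_tornado_params(config: RunConfig,
                           cost_range: float = 0.25) -> list[tuple[str, float, float]]:
    """Cost parameters ranged ±25% (as scale factors); epidemiology
    parameters get explicit low/high values around their base."""
    params: list[tuple[str, float, float]] = []
    for name in config.regimens:
        params.append((f"cost_scale.{name}", 1.0 - cost_range, 1.0 + cost_range))
    params.append(("cost_scale.test", 1.0 - cost_range, 1.0 + cost_range))
    prev = config.prevalence
    params.append(("epidemiology.prevalence",
                   max(prev - 0.1, 0.0), min(prev + 0.1, 1.0)))
    punk = config.test.p_unknown
    params.append(("epidemiology.p_unknown",
                   max(punk - 0.05, 0.0), min(punk + 0.05, 1.0)))
    return params


def tornado_model(base_config: RunConfig,
                  curves: Mapping[str, Sequence[SurvivalCurve]],
                  wtp: float = 30_000.0,
                  intervention: str = "testing",
                  comparator: str = "no_testing") -> Callable[[str, float], float]:
    """Summary-statistic callable for :func:`tornado`.

    Reports the ICER when the base-case comparison defines one; otherwise
    (the base case is dominant/dominated) reports the incremental net
    monetary benefit at the willingness-to-pay threshold ``wtp``, which is
    sign-stable where the ICER is not.
    """
    base = evaluate(base_config, curves, intervention, comparator)
    use_icer = base.comparison is not None and base.comparison.verdict == "icer"

    def model(name: str, value: float) -> float:
        res = run_scenario(base_config, {name: value}, curves,
                           intervention=intervention, comparator=comparator)
        cmp_ = res.comparison
        if use_icer and cmp_.verdict == "icer":
            return cmp_.icer
        return wtp * cmp_.incr_effect - cmp_.incr_cost

    return model
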