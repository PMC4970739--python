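"""Monthly semi-Markov cohort model of sequential cancer treatment lines.

A cohort enters first-line treatment and moves through progression events
into later lines, ending in best supportive care (BSC) after the final
progression; death can occur from any state. Transition probabilities are
time-variant and indexed by time since line entry (a semi-Markov clock),
implemented with clock-expanded states: trial PFS/OS curves are measured
from the start of the line they describe, which is only coherent if each
line's schedule restarts on entry.

Competing risks within a cycle are split with death taking priority:
the progression probability is the PFS-event probability minus the death
probability, floored at zero. Deaths evaluated at the start of a cycle
contribute no cost or utility for that cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .survival_models import TransitionSchedule

log = logging.getLogger(__name__)

__all__ = [
    "TreatmentLine",
    "StrategyDefinition",
    "CycleConfig",
    "ArmTrace",
    "CohortTrace",
    "run_cohort",
    "accumulate_costs",
    "accumulate_qalys",
]


@dataclass(frozen=True)
class TreatmentLine:
    """One treatment line and its clinical/economic inputs.

    ``pfs_schedule`` is None for a terminal BSC line (no further
    progression). ``admin_cycles`` is the number of clock cycles billed at
    the administration cost (4 for a four-cycle chemotherapy regimen; the
    whole horizon for continuously dosed oral therapy and for BSC).
    ``utility_adjustment`` carries route-of-administration corrections
    (e.g. +0.02 for oral dosing); ``ae_disutility_total`` is the summed
    adverse-event disutility applied for the first ``ae_cycles`` clock
    cycles (base case: the entry cycle only).
    """

    label: str
    os_schedule: TransitionSchedule
    pfs_schedule: TransitionSchedule | None = None
    cost_admin_per_cycle: float = 0.0
    cost_nonadmin_per_cycle: float = 0.0
    admin_cycles: int = 0
    utility: float = 0.0
    utility_adjustment: float = 0.0
    ae_disutility_total: float = 0.0
    ae_cycles: int = 1
    is_oral: bool = False

    def __post_init__(self) -> None:
        if self.cost_admin_per_cycle < 0 or self.cost_nonadmin_per_cycle < 0:
            raise ValueError(f"line {self.label!r}: negative cost")
        if not (0.0 <= self.utility <= 1.0):
            raise ValueError(f"line {self.label!r}: utility outside [0, 1]")
        if self.admin_cycles < 0 or self.ae_cycles < 0:
            raise ValueError(f"line {self.label!r}: negative cycle count")

    @property
    def effective_utility(self) -> float:
        u = self.utility + self.utility_adjustment
        if not (-0.2 <= u <= 1.0):
            raise ValueError(
                f"line {self.label!r}: effective utility {u} outside [-0.2, 1]"
            )
        return u


@dataclass(frozen=True)
class StrategyDefinition:
    """A treatment strategy: weighted decision-tree arms, each an ordered
    list of treatment lines ending in BSC, plus a one-off test cost."""

    name: str
    arms: tuple[tuple[float, tuple[TreatmentLine, ...]], ...]
    test_cost: float = 0.0

    def __init__(self, name, arms, test_cost=0.0):
        arms = tuple((float(w), tuple(path)) for w, path in arms)
        if not arms:
            raise ValueError("strategy needs at least one arm")
        wsum = sum(w for w, _ in arms)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"arm weights sum to {wsum}, expected 1")
        for _, path in arms:
            if not path:
                raise ValueError("empty pathway")
            if path[-1].pfs_schedule is not None:
                raise ValueError(
                    f"pathway must end in a terminal (BSC) line; got {path[-1].label!r}"
                )
        if test_cost < 0:
            raise ValueError("negative test cost")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "arms", arms)
        object.__setattr__(self, "test_cost", float(test_cost))


@dataclass(frozen=True)
class CycleConfig:
    """Cycle length is fixed at one month; horizon in cycles."""

    horizon: int = 60
    annual_discount_rate: float = 0.03
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be ≥ 1")
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be ≥ 0")

    def discount_factors(self) -> np.ndarray:
        """Monthly factors (1+r)^(−t/12) for t = 0..horizon−1; with
        half-cycle correction the stream is discounted at mid-cycle."""
        t = np.arange(self.horizon, dtype=float)
        if self.half_cycle_correction:
            t = t + 0.5
        return (1.0 + self.annual_discount_rate) ** (-t / 12.0)


@dataclass
class ArmTrace:
    """State occupancy for one decision-tree arm.

    ``occupancy[t, l, τ]`` is the fraction of the arm cohort in line ``l``
    with clock ``τ`` (cycles since line entry) at the start of cycle ``t``;
    ``dead[t]`` is the absorbing dead fraction.
    """

    weight: float
    lines: tuple[TreatmentLine, ...]
    occupancy: np.ndarray
    dead: np.ndarray

    def alive(self) -> np.ndarray:
        return self.occupancy.sum(axis=(1, 2))

    def check_conservation(self, tol: float = 1e-10) -> None:
        total = self.alive() + self.dead
        if np.any(np.abs(total - 1.0) > tol):
            raise AssertionError("occupancy not conserved")


@dataclass
class CohortTrace:
    """Per-arm traces for a whole strategy; arm weights sum to 1."""

    strategy: str
    horizon: int
    arms: list[ArmTrace] = field(default_factory=list)

    def dead(self) -> np.ndarray:
        """Cohort-level dead fraction per cycle (weighted over arms)."""
        return sum(a.weight * a.dead for a in self.arms)

    def alive(self) -> np.ndarray:
        return sum(a.weight * a.alive() for a in self.arms)


def _run_arm(weight: float, lines: tuple[TreatmentLine, ...], config: CycleConfig) -> ArmTrace:
    H = config.horizon
    L = len(lines)
    for line in lines:
        if len(line.os_schedule) < H:
            raise ValueError(f"line {line.label!r}: OS schedule shorter than horizon")
        if line.pfs_schedule is not None and len(line.pfs_schedule) < H:
            raise ValueError(f"line {line.label!r}: PFS schedule shorter than horizon")

    occ = np.zeros((H + 1, L, H + 1))
    dead = np.zeros(H + 1)
    occ[0, 0, 0] = 1.0
    clamped = 0

    for t in range(H):
        dead[t + 1] = dead[t]
        for l, line in enumerate(lines):
            for tau in range(t + 1):
                frac = occ[t, l, tau]
                if frac == 0.0:
                    continue
                p_death = line.os_schedule[tau]
                if line.pfs_schedule is None:
                    p_prog = 0.0
                else:
                    p_event = line.pfs_schedule[tau]
                    p_prog = p_event - p_death
                    if p_prog < 0.0:
                        clamped += 1
                        p_prog = 0.0
                # death takes priority; remainder stays with clock + 1
                dead[t + 1] += frac * p_death
                if p_prog > 0.0:
                    occ[t + 1, l + 1, 0] += frac * p_prog
                occ[t + 1, l, tau + 1] += frac * (1.0 - p_death - p_prog)
    if clamped:
        log.warning("%d negative progression probabilities clamped to 0", clamped)
    return ArmTrace(weight=weight, lines=lines, occupancy=occ, dead=dead)


def run_cohort(strategy: StrategyDefinition, config: CycleConfig) -> CohortTrace:
    """Propagate the cohort through every arm of the strategy."""
    trace = CohortTrace(strategy=strategy.name, horizon=config.horizon)
    for weight, path in strategy.arms:
        arm = _run_arm(weight, path, config)
        arm.check_conservation()
        trace.arms.append(arm)
    return trace


def accumulate_costs(trace: CohortTrace, strategy: StrategyDefinition,
                     config: CycleConfig) -> float:
    """Discounted per-patient cost over the horizon.

    Each occupied cycle is billed at the administration cost while the line
    clock is below ``admin_cycles`` and at the non-administration cost
    afterwards; the test cost falls on the full cohort at cycle 0,
    undiscounted.
    """
    H = config.horizon
    disc = config.discount_factors()
    total = strategy.test_cost
    for arm in trace.arms:
        stream = np.zeros(H)
        for l, line in enumerate(arm.lines):
            per_clock = np.where(
                np.arange(H + 1) < line.admin_cycles,
                line.cost_admin_per_cycle, line.cost_nonadmin_per_cycle)
            stream += arm.occupancy[:H, l, :] @ per_clock
        total += arm.weight * float(stream @ disc)
    return total


def accumulate_qalys(trace: CohortTrace, strategy: StrategyDefinition,
                     config: CycleConfig) -> float:
    """Discounted per-patient QALYs over the horizon.

    Each occupied cycle contributes utility/12; adverse-event disutility is
    subtracted for the first ``ae_cycles`` clock cycles of each line (base
    case: entry cycle only).
    """
    H = config.horizon
    disc = config.discount_factors()
    total = 0.0
    for arm in trace.arms:
        stream = np.zeros(H)
        for l, line in enumerate(arm.lines):
            per_clock = np.full(H + 1, line.effective_utility)
            per_clock[: line.ae_cycles] -= line.ae_disutility_total
            stream += arm.occupancy[:H, l, :] @ (per_clock / 12.0)
        total += arm.weight * float(stream @ disc)
    return total
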