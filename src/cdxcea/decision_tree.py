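"""Decision-tree branch proportions for a test-and-treat strategy.

A companion-diagnostic test with known sensitivity and specificity splits a
cohort with given biomarker prevalence into true/false positives and
negatives; a fraction of specimens is inadequate for genotyping ("unknown")
and bypasses the classification entirely. Unknown-result patients are
routed down the test-negative (chemotherapy) pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TestPerformance", "BranchProportions", "branch_proportions"]


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class TestPerformance:
    """Diagnostic accuracy of the mutation test."""

    sensitivity: float
    specificity: float
    p_unknown: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "p_unknown"):
            _check_prob(name, getattr(self, name))


@dataclass(frozen=True)
class BranchProportions:
    """Cohort split over the five decision-tree branches.

    ``p_tp + p_fp + p_tn + p_fn + p_unknown = 1``. Test-positive patients
    (true or false) receive the targeted-therapy pathway; test-negative and
    unknown patients receive the chemotherapy pathway.
    """

    p_tp: float
    p_fp: float
    p_tn: float
    p_fn: float
    p_unknown: float

    def __post_init__(self) -> None:
        total = self.p_tp + self.p_fp + self.p_tn + self.p_fn + self.p_unknown
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"branch proportions sum to {total}, expected 1")

    @property
    def p_test_positive(self) -> float:
        return self.p_tp + self.p_fp

    @property
    def p_test_negative(self) -> float:
        return self.p_tn + self.p_fn

    @property
    def p_chemo_pathway(self) -> float:
        """Test-negative plus unknown: everyone on first-line chemotherapy."""
        return self.p_test_negative + self.p_unknown


def branch_proportions(prevalence: float, perf: TestPerformance) -> BranchProportions:
    """Evaluate the branch formulas.

    p_tp = prev·sens·(1−pU), p_fp = (1−prev)·(1−spec)·(1−pU),
    p_tn = (1−prev)·spec·(1−pU), p_fn = prev·(1−sens)·(1−pU),
    with the unknown fraction pU taken off the top.
    """
    prev = _check_prob("prevalence", prevalence)
    known = 1.0 - perf.p_unknown
    return BranchProportions(
        p_tp=prev * perf.sensitivity * known,
        p_fp=(1.0 - prev) * (1.0 - perf.specificity) * known,
        p_tn=(1.0 - prev) * perf.specificity * known,
        p_fn=prev * (1.0 - perf.sensitivity) * known,
        p_unknown=perf.p_unknown,
    )
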