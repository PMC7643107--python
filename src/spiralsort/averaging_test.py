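"""Bisection refinement of a focusing threshold from recovery-rate data.

The "averaging test" repeatedly measures the highest per-outlet recovery rate
(hPRR) at the midpoint of a diameter bracket and compares it against a
well-focused reference.  "Same as reference" means the true threshold is at or
below the midpoint (narrow down); "significantly lower" means it is above
(narrow up).  The procedure stops when the bracket is narrower than a
tolerance and proposes the final upper bound as the refined threshold.

Statistical rule: one-sided Welch two-sample t-test on replicate hPRRs,
H1: mean(test) < mean(reference), at level ``alpha`` (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientReplicatesError, InvalidBracketError

Decision = Literal["same", "lower"]


@dataclass(frozen=True)
class PRRMeasurement:
    """Replicate hPRR percentages observed for one test diameter (um)."""

    test_diameter: float
    replicate_hprrs: tuple[float, ...]
    outlet: int | None = None

    def __init__(
        self,
        test_diameter: float,
        replicate_hprrs: Sequence[float],
        outlet: int | None = None,
    ) -> None:
        reps = tuple(float(r) for r in replicate_hprrs)
        for r in reps:
            if not 0.0 <= r <= 100.0:
                raise DomainError(f"hPRR replicate {r} outside [0, 100]%")
        object.__setattr__(self, "test_diameter", float(test_diameter))
        object.__setattr__(self, "replicate_hprrs", reps)
        object.__setattr__(self, "outlet", outlet)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_hprrs))


@dataclass
class AveragingTestTrace:
    """Full record of one bisection run."""

    bracket_low: float
    bracket_high: float
    steps: list[tuple[float, Decision]] = field(default_factory=list)
    proposed_threshold: float = math.nan
    final_bracket: tuple[float, float] = (math.nan, math.nan)

    def midpoints(self) -> list[float]:
        return [d for d, _ in self.steps]


def compare_hprr(
    test: PRRMeasurement, reference: PRRMeasurement, alpha: float = 0.05
) -> Decision:
    """'lower' if the test hPRR is significantly below the reference, else 'same'.

    One-sided Welch t-test on the replicates.  Degenerate zero-variance groups
    (deterministic oracles) are decided by comparing means directly.
    """
    if len(test.replicate_hprrs) < 2 or len(reference.replicate_hprrs) < 2:
        raise InsufficientReplicatesError(
            "need >= 2 replicates per group for a statistical comparison"
        )
    a = np.asarray(test.replicate_hprrs, dtype=float)
    b = np.asarray(reference.replicate_hprrs, dtype=float)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:  # both groups constant
        return "lower" if a[0] < b[0] else "same"
    result = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return "lower" if result.pvalue < alpha else "same"


def averaging_test_step(
    bracket: tuple[float, float],
    decision: Decision,
    midpoint: float | None = None,
) -> tuple[float, float]:
    """Narrow the bracket around its midpoint according to the decision.

    'same' keeps the lower half (threshold at or below the midpoint); 'lower'
    keeps the upper half.  An explicit ``midpoint`` overrides ``(low+high)/2``
    (used by the display-rounding mode).
    """
    low, high = bracket
    if low >= high:
        raise InvalidBracketError(f"bracket ({low}, {high}) has non-positive width")
    m = (low + high) / 2.0 if midpoint is None else midpoint
    if not low < m < high:
        raise InvalidBracketError(f"midpoint {m} outside bracket ({low}, {high})")
    if decision == "same":
        return (low, m)
    if decision == "lower":
        return (m, high)
    raise DomainError(f"decision must be 'same' or 'lower', got {decision!r}")


def _truncate_to_tenth(x: float) -> float:
    """Truncate to 0.1 (the display granularity used for reported midpoints)."""
    return math.floor(x * 10.0 + 1e-9) / 10.0


def run_averaging_test(
    low: float,
    high: float,
    oracle: Callable[[float], "PRRMeasurement | Decision"],
    reference: PRRMeasurement | None = None,
    tol: float = 0.5,
    alpha: float = 0.05,
    display_rounding: bool = False,
) -> AveragingTestTrace:
    """Bisect ``[low, high]`` (um) down to width ``tol`` and propose a threshold.

    ``oracle(diameter)`` returns either a :class:`PRRMeasurement` (compared
    against ``reference`` with :func:`compare_hprr`) or a decision string
    directly.  With ``display_rounding=True`` each midpoint is truncated to
    0.1 um before testing and the truncated value is carried into the next
    bracket, mirroring how refined thresholds are quoted in practice.

    The proposed threshold is the final bracket's upper bound — the smallest
    diameter demonstrated to focus as well as the reference.
    """
    if not low < high:
        raise InvalidBracketError(f"bracket ({low}, {high}) has non-positive width")
    if tol <= 0:
        raise DomainError("tolerance must be positive")
    trace = AveragingTestTrace(bracket_low=low, bracket_high=high)
    lo, hi = low, high
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if display_rounding:
            mid = _truncate_to_tenth(mid)
        try:
            outcome = oracle(mid)
        except Exception as exc:
            raise RuntimeError(
                f"oracle failed at step {len(trace.steps) + 1} (diameter {mid} um)"
            ) from exc
        if isinstance(outcome, str):
            decision: Decision = outcome  # type: ignore[assignment]
            if decision not in ("same", "lower"):
                raise DomainError(f"oracle returned invalid decision {decision!r}")
        else:
            if reference is None:
                raise DomainError("a reference measurement is required to compare hPRRs")
            decision = compare_hprr(outcome, reference, alpha)
        trace.steps.append((mid, decision))
        lo, hi = averaging_test_step((lo, hi), decision, midpoint=mid)
    trace.final_bracket = (lo, hi)
    trace.proposed_threshold = hi
    return trace
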