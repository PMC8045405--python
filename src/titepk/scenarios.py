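"""Simulation scenarios: true DLT probabilities per dose and schedule.

Scenarios 1-6 are single-schedule (daily) trials over doses 2.5-15 mg;
Scenarios 7-13 are sequential trials whose first schedule doses every 48
hours and whose second schedule doses daily, over the same dose grid.
Scenario 13 deliberately violates the exposure-monotonicity assumption: the
less frequent schedule is the more toxic one.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScheduleArm", "Scenario", "SCENARIOS", "DOSE_GRID"]

DOSE_GRID = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0)


@dataclass(frozen=True)
class ScheduleArm:
    """One schedule's dose grid with its true per-dose DLT probabilities."""

    label: str
    interval: float  # hours between administrations
    doses: tuple[float, ...]
    true_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.true_probs):
            raise ValueError("doses and true_probs must align")
        if not self.doses:
            raise ValueError("dose grid must be nonempty")
        if any(not (0 <= p <= 1) for p in self.true_probs):
            raise ValueError("true probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    sid: int
    arms: tuple[ScheduleArm, ...]

    @property
    def sequential(self) -> bool:
        return len(self.arms) > 1


def _single(sid: int, probs) -> Scenario:
    return Scenario(sid, (ScheduleArm("daily", 24.0, DOSE_GRID, tuple(probs)),))


def _seq(sid: int, probs1, probs2) -> Scenario:
    return Scenario(
        sid,
        (
            ScheduleArm("q48h", 48.0, DOSE_GRID, tuple(probs1)),
            ScheduleArm("daily", 24.0, DOSE_GRID, tuple(probs2)),
        ),
    )


SCENARIOS: dict[int, Scenario] = {
    1: _single(1, (0.05, 0.10, 0.20, 0.30, 0.50, 0.70)),
    2: _single(2, (0.30, 0.40, 0.52, 0.61, 0.76, 0.87)),
    3: _single(3, (0.05, 0.06, 0.08, 0.11, 0.19, 0.34)),
    4: _single(4, (0.06, 0.08, 0.12, 0.18, 0.40, 0.71)),
    5: _single(5, (0.10, 0.22, 0.31, 0.45, 0.60, 0.72)),
    6: _single(6, (0.50, 0.55, 0.61, 0.69, 0.76, 0.87)),
    7: _seq(7, (0.05, 0.07, 0.09, 0.10, 0.13, 0.18), (0.08, 0.12, 0.16, 0.18, 0.23, 0.27)),
    8: _seq(8, (0.08, 0.12, 0.16, 0.20, 0.23, 0.27), (0.18, 0.26, 0.34, 0.45, 0.49, 0.55)),
    9: _seq(9, (0.03, 0.12, 0.28, 0.40, 0.54, 0.62), (0.20, 0.30, 0.45, 0.50, 0.60, 0.75)),
    10: _seq(10, (0.10, 0.20, 0.34, 0.40, 0.49, 0.55), (0.35, 0.40, 0.45, 0.57, 0.67, 0.80)),
    11: _seq(11, (0.05, 0.07, 0.09, 0.15, 0.22, 0.28), (0.30, 0.35, 0.48, 0.52, 0.61, 0.70)),
    12: _seq(12, (0.45, 0.50, 0.55, 0.65, 0.75, 0.85), (0.48, 0.56, 0.62, 0.70, 0.80, 0.88)),
    13: _seq(13, (0.18, 0.26, 0.34, 0.45, 0.49, 0.55), (0.08, 0.12, 0.16, 0.18, 0.23, 0.27)),
}
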