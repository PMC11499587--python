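"""Growth-stage binning over the full-heading-to-maturity interval.

A plot's interval from full heading (80% of panicles headed) to maturity is
split into equal thirds; an acquisition day is assigned to one of them, or
excluded as pre-heading / post-maturity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import IncompleteHeadingError


class StageLabel(str, Enum):
    PRE_HEADING = "pre_heading"
    FIRST_THIRD = "first_third"
    SECOND_THIRD = "second_third"
    FINAL_THIRD = "final_third"
    POST_MATURITY = "post_maturity"


#: stages whose images enter the panicle datasets
DATASET_STAGES = (StageLabel.FIRST_THIRD, StageLabel.SECOND_THIRD, StageLabel.FINAL_THIRD)


@dataclass(frozen=True)
class PlotCalendar:
    """Per-plot full-heading and maturity days (days after sowing)."""

    plot_id: str
    fhs_day: float
    ms_day: float

    def __post_init__(self) -> None:
        if not self.fhs_day < self.ms_day:
            raise ValueError(
                f"plot {self.plot_id}: fhs_day {self.fhs_day} must precede ms_day {self.ms_day}"
            )


def assign_stage(calendar: PlotCalendar, acq_day: float) -> StageLabel:
    """Assign an acquisition day to a third of the heading-to-maturity span.

    The three thirds are half-open on the left, except that the maturity day
    itself closes the final third.  Days before full heading or after
    maturity fall outside the dataset stages.
    """
    if acq_day < 0:
        raise ValueError("acq_day must be non-negative")
    fhs, ms = calendar.fhs_day, calendar.ms_day
    if acq_day < fhs:
        return StageLabel.PRE_HEADING
    if acq_day > ms:
        return StageLabel.POST_MATURITY
    d = ms - fhs
    if acq_day < fhs + d / 3.0:
        return StageLabel.FIRST_THIRD
    if acq_day < fhs + 2.0 * d / 3.0:
        return StageLabel.SECOND_THIRD
    return StageLabel.FINAL_THIRD


def heading_duration(series: list[tuple[float, float]]) -> float:
    """Days between 10% and 80% heading, by linear interpolation.

    ``series`` is (day, heading ratio) sorted by day.  Ratios are made
    non-decreasing with a running maximum first (heading is cumulative, so
    apparent dips are measurement noise).
    """
    if len(series) < 2:
        raise IncompleteHeadingError("need at least two observations")
    days = np.asarray([d for d, _ in series], dtype=float)
    if not np.all(np.diff(days) >= 0):
        raise ValueError("series must be sorted by day")
    ratios = np.maximum.accumulate(np.asarray([r for _, r in series], dtype=float))

    def crossing(target: float) -> float:
        if ratios[0] > target or ratios[-1] < target:
            raise IncompleteHeadingError(
                f"series does not bracket heading ratio {target}"
            )
        i = int(np.searchsorted(ratios, target, side="left"))
        if ratios[i] == target and (i == 0 or ratios[i - 1] < target):
            # exact hit; take the first day achieving it
            pass
        if i == 0:
            return float(days[0])
        r0, r1 = ratios[i - 1], ratios[i]
        if r1 == r0:
            return float(days[i])
        return float(days[i - 1] + (days[i] - days[i - 1]) * (target - r0) / (r1 - r0))

    return crossing(0.80) - crossing(0.10)
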