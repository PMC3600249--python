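"""Survival-time stratification and group-level summaries.

The cohort design records, for each patient, the number of whole days from
CBC sampling to death (every subject died within a year).  Patients are
stratified into eight survival groups — Day 1 through Day 5 singly, then
Days 6–30, Days 31–180 and Days 181–365 — which partition [1, 365] with no
gaps or overlaps.  Fine resolution in the first five days reflects the
CBC's responsiveness to imminent death; the wider late bins collect the
longer-term deaths.

Group summaries report, per group: patient count, median survival day,
mean ± SD of each CBC parameter over present values (sample SD, n−1
denominator), and the 25th/50th/75th percentiles of the prognostic score
over scorable records.  Quantiles use linear interpolation between order
statistics at fractional position ``h = p·(n−1)`` (numpy's "linear"
method), fixed and documented because quartile conventions differ at
small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import OutOfStudyRangeError
from .patients import PatientRecord, STUDY_MAX_SURVIVAL_DAYS
from .reference import CbcParameter, ReferenceRange
from .scoring import DEFAULT_SELECTED, UnscorableRecord, score_cohort

__all__ = [
    "SurvivalGroup",
    "SURVIVAL_GROUPS",
    "GroupSummary",
    "assign_group",
    "quantile",
    "summarize_groups",
    "PatientRecord",
]


@dataclass(frozen=True)
class SurvivalGroup:
    """One survival-time stratum: a label and an inclusive day range."""

    label: str
    day_lo: int
    day_hi: int

    def contains(self, survival_days: int) -> bool:
        return self.day_lo <= survival_days <= self.day_hi


#: The eight survival groups, in order; they partition [1, 365].
SURVIVAL_GROUPS: tuple[SurvivalGroup, ...] = (
    SurvivalGroup("Day 1", 1, 1),
    SurvivalGroup("Day 2", 2, 2),
    SurvivalGroup("Day 3", 3, 3),
    SurvivalGroup("Day 4", 4, 4),
    SurvivalGroup("Day 5", 5, 5),
    SurvivalGroup("Days 6-30", 6, 30),
    SurvivalGroup("Days 31-180", 31, 180),
    SurvivalGroup("Days 181-365", 181, 365),
)


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one survival group.

    ``per_parameter`` maps each CBC parameter to ``(mean, sd)`` over
    present values (NaN when no value is present; sd is NaN for n=1).
    ``score_quartiles`` holds the (q25, q50, q75) of the prognostic score
    over scorable records, or ``None`` when none is scorable.
    """

    group: SurvivalGroup
    n: int
    survival_median: float
    per_parameter: Mapping[CbcParameter, tuple[float, float]]
    score_quartiles: tuple[float, float, float] | None
    n_scored: int = 0
    unscorable: tuple[UnscorableRecord, ...] = ()


def assign_group(survival_days: int) -> SurvivalGroup:
    """The unique survival group whose day range contains ``survival_days``.

    Raises
    ------
    OutOfStudyRangeError
        If ``survival_days`` is outside [1, 365] — such a patient does not
        meet the study inclusion criteria.
    """
    if not (1 <= survival_days <= STUDY_MAX_SURVIVAL_DAYS):
        raise OutOfStudyRangeError(
            f"survival_days={survival_days!r} outside study range "
            f"[1, {STUDY_MAX_SURVIVAL_DAYS}]"
        )
    for g in SURVIVAL_GROUPS:
        if g.contains(survival_days):
            return g
    raise AssertionError("unreachable: groups partition [1, 365]")


def quantile(values: Sequence[float], p: float) -> float:
    """Quantile by linear interpolation between order statistics.

    On the sorted values ``v[0..n-1]``, returns
    ``v[⌊h⌋] + (h−⌊h⌋)·(v[⌊h⌋+1] − v[⌊h⌋])`` with ``h = p·(n−1)``;
    for odd n, ``p=0.5`` is exactly the middle element.

    Raises
    ------
    ValueError
        On empty input or p outside [0, 1].
    """
    if len(values) == 0:
        raise ValueError("quantile of empty sequence")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    return float(np.quantile(np.asarray(values, dtype=float), p, method="linear"))


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    return mean, sd


def summarize_groups(
    records: Sequence[PatientRecord],
    panel: Mapping[CbcParameter, ReferenceRange],
    selected: Iterable[CbcParameter] = DEFAULT_SELECTED,
    *,
    require_complete: bool = False,
) -> list[GroupSummary]:
    """Stratify a cohort into the eight survival groups and summarize each.

    Returns exactly eight :class:`GroupSummary` objects in group order.
    Empty groups carry ``n=0``, NaN summaries and no quartiles.
    """
    selected = frozenset(selected)
    by_group: dict[SurvivalGroup, list[PatientRecord]] = {
        g: [] for g in SURVIVAL_GROUPS
    }
    for r in records:
        by_group[assign_group(r.survival_days)].append(r)

    summaries: list[GroupSummary] = []
    for g in SURVIVAL_GROUPS:
        members = by_group[g]
        n = len(members)
        survival_median = (
            float(np.median([r.survival_days for r in members])) if members else math.nan
        )
        per_parameter = {
            param: _mean_sd(
                [v for r in members if (v := r.value(param)) is not None]
            )
            for param in CbcParameter
        }
        scores, unscorable = score_cohort(
            members, panel, selected, require_complete=require_complete
        )
        score_values = [s.value for s in scores]
        quartiles = (
            (
                quantile(score_values, 0.25),
                quantile(score_values, 0.50),
                quantile(score_values, 0.75),
            )
            if score_values
            else None
        )
        summaries.append(
            GroupSummary(
                group=g,
                n=n,
                survival_median=survival_median,
                per_parameter=per_parameter,
                score_quartiles=quartiles,
                n_scored=len(score_values),
                unscorable=tuple(unscorable),
            )
        )
    return summaries
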