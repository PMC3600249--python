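"""Synthetic critically ill cohorts with the study's group structure.

The generator emulates the marginal structure of the source cohort: eight
survival groups of fixed sizes (59, 64, 29, 21, 34, 38, 37, 24 — total
306), each with its own per-parameter mean ± SD for the five CBC
measurements.  Within a group, each CBC value is drawn independently from
a normal distribution with the group's (mean, sd), redrawn until it
reaches a small positive floor (rejection-truncated at 0.01 by default, so
no clamping point mass distorts the means).  Survival times are the fixed
day for the Day 1–Day 5 groups; for the three interval groups they are,
by default, uniform integers over the group's day range, with an optional
median-matched preset that reproduces the observed group medians
(14, 91, 296) via a two-piece uniform mixture.

Only marginals are modelled: CBC parameters are independent within a
group (no cross-parameter covariance), so cohort-level rank correlations
with survival arise purely from between-group mean shifts.  Their *signs*
are reproducible; their magnitudes are not calibrated to any real cohort.
Missingness can be switched on per value at a configurable rate
(default 0).

Default group parameters (mean ± SD):

    group          n   Neu          Lym        RBC        HB            Plt
    Day 1          59  14.0 ± 11.3  2.1 ± 1.9  3.5 ± 1.2  108.1 ± 34.2  140.5 ± 101.8
    Day 2          64  12.3 ± 6.5   1.4 ± 1.0  3.6 ± 1.2  111.1 ± 38.3  150.3 ± 102.0
    Day 3          29  9.5 ± 5.6    0.9 ± 0.6  3.7 ± 1.1  111.5 ± 34.8  138.1 ± 75.2
    Day 4          21  10.6 ± 7.3   1.5 ± 1.3  3.5 ± 1.0  107.3 ± 30.5  152.4 ± 94.1
    Day 5          34  10.9 ± 7.1   1.2 ± 0.7  3.6 ± 0.8  107.3 ± 26.1  167.0 ± 81.0
    Days 6-30      38  10.1 ± 5.4   1.2 ± 0.7  3.4 ± 0.7  106.5 ± 22.1  171.8 ± 100.1
    Days 31-180    37  6.9 ± 4.5    1.4 ± 0.7  3.7 ± 0.8  114.4 ± 22.2  209.9 ± 102.2
    Days 181-365   24  5.2 ± 3.0    1.6 ± 0.7  4.0 ± 0.8  121.8 ± 28.7  223.3 ± 92.8
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .groups import SURVIVAL_GROUPS, SurvivalGroup, assign_group
from .patients import PatientRecord
from .reference import CbcParameter, Measurement

__all__ = [
    "SurvivalSampling",
    "GroupSpec",
    "SimulationConfig",
    "default_group_specs",
    "median_matched_group_specs",
    "generate_cohort",
    "empirical_check",
    "EmpiricalCheckReport",
]


class SurvivalSampling(enum.Enum):
    """How survival days are drawn within a group's day range."""

    FIXED = "fixed"              # always the group's single day
    UNIFORM = "uniform"          # uniform integer over [lo, hi]
    MEDIAN_MATCHED = "median_matched"  # two-piece uniform hitting a target median


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one survival group.

    ``per_parameter`` maps each CBC parameter to its (mean, sd); sd may be
    0 (degenerate distribution at the mean).  ``median_day`` is used only
    by MEDIAN_MATCHED sampling.
    """

    group: SurvivalGroup
    n: int
    per_parameter: Mapping[CbcParameter, tuple[float, float]]
    survival_sampling: SurvivalSampling = SurvivalSampling.UNIFORM
    median_day: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"{self.group.label}: n must be >= 0, got {self.n}")
        for param, (mean, sd) in self.per_parameter.items():
            if sd < 0:
                raise ValidationError(
                    f"{self.group.label}/{param.name}: sd must be >= 0, got {sd}"
                )
        if self.survival_sampling is SurvivalSampling.MEDIAN_MATCHED:
            m = self.median_day
            if m is None or not (self.group.day_lo <= m <= self.group.day_hi):
                raise ValidationError(
                    f"{self.group.label}: median_day {m!r} outside day range"
                )


# (n, Neu, Lym, RBC, HB, Plt) per group, with the observed median day.
_DEFAULT_ROWS: tuple[tuple[int, int, tuple[tuple[float, float], ...]], ...] = (
    (1, 59, ((14.0, 11.3), (2.1, 1.9), (3.5, 1.2), (108.1, 34.2), (140.5, 101.8))),
    (2, 64, ((12.3, 6.5), (1.4, 1.0), (3.6, 1.2), (111.1, 38.3), (150.3, 102.0))),
    (3, 29, ((9.5, 5.6), (0.9, 0.6), (3.7, 1.1), (111.5, 34.8), (138.1, 75.2))),
    (4, 21, ((10.6, 7.3), (1.5, 1.3), (3.5, 1.0), (107.3, 30.5), (152.4, 94.1))),
    (5, 34, ((10.9, 7.1), (1.2, 0.7), (3.6, 0.8), (107.3, 26.1), (167.0, 81.0))),
    (14, 38, ((10.1, 5.4), (1.2, 0.7), (3.4, 0.7), (106.5, 22.1), (171.8, 100.1))),
    (91, 37, ((6.9, 4.5), (1.4, 0.7), (3.7, 0.8), (114.4, 22.2), (209.9, 102.2))),
    (296, 24, ((5.2, 3.0), (1.6, 0.7), (4.0, 0.8), (121.8, 28.7), (223.3, 92.8))),
)

_PARAM_ORDER = (
    CbcParameter.NEU,
    CbcParameter.LYM,
    CbcParameter.RBC,
    CbcParameter.HB,
    CbcParameter.PLT,
)


def default_group_specs() -> tuple[GroupSpec, ...]:
    """The eight default group specs (fixed day for Day 1–5, uniform
    integer survival within the interval groups)."""
    specs = []
    for group, (median_day, n, stats_row) in zip(SURVIVAL_GROUPS, _DEFAULT_ROWS):
        sampling = (
            SurvivalSampling.FIXED
            if group.day_lo == group.day_hi
            else SurvivalSampling.UNIFORM
        )
        specs.append(
            GroupSpec(
                group=group,
                n=n,
                per_parameter=dict(zip(_PARAM_ORDER, stats_row)),
                survival_sampling=sampling,
                median_day=median_day,
            )
        )
    return tuple(specs)


def median_matched_group_specs() -> tuple[GroupSpec, ...]:
    """Default specs with interval-group survival sampling replaced by the
    two-piece uniform that matches the observed group medians (14, 91, 296).

    A symmetric uniform cannot place the Days 181–365 median at 296, so
    half the mass is drawn uniformly from [lo, median] and half from
    [median+1, hi]."""
    return tuple(
        spec
        if spec.survival_sampling is SurvivalSampling.FIXED
        else replace(spec, survival_sampling=SurvivalSampling.MEDIAN_MATCHED)
        for spec in default_group_specs()
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one synthetic cohort draw."""

    seed: int
    group_specs: tuple[GroupSpec, ...] = field(default_factory=default_group_specs)
    missingness_rate: float = 0.0
    value_floor: float = 0.01

    def __post_init__(self) -> None:
        if len(self.group_specs) != len(SURVIVAL_GROUPS):
            raise ValidationError(
                f"expected {len(SURVIVAL_GROUPS)} group specs, "
                f"got {len(self.group_specs)}"
            )
        if not (0.0 <= self.missingness_rate < 1.0):
            raise ValidationError(
                f"missingness_rate must be in [0, 1), got {self.missingness_rate}"
            )
        if not self.value_floor > 0:
            raise ValidationError(
                f"value_floor must be positive, got {self.value_floor}"
            )

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.group_specs)


def _draw_survival(spec: GroupSpec, rng: np.random.Generator) -> int:
    g = spec.group
    if spec.survival_sampling is SurvivalSampling.FIXED:
        return g.day_lo
    if spec.survival_sampling is SurvivalSampling.UNIFORM:
        return int(rng.integers(g.day_lo, g.day_hi + 1))
    # MEDIAN_MATCHED: validated to have a median_day inside the range
    m = spec.median_day
    if rng.random() < 0.5:
        return int(rng.integers(g.day_lo, m + 1))
    return int(rng.integers(m + 1, g.day_hi + 1))


def _draw_value(
    mean: float, sd: float, floor: float, rng: np.random.Generator
) -> float:
    """Normal draw rejection-truncated below at ``floor``."""
    if sd == 0.0:
        if mean < floor:
            raise ValidationError(
                f"degenerate value {mean} below floor {floor}; unsatisfiable"
            )
        return mean
    for _ in range(100_000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return float(x)
    raise ValidationError(
        f"rejection sampling failed: N({mean}, {sd}) mass above {floor} "
        "is negligible"
    )


def generate_cohort(cfg: SimulationConfig) -> list[PatientRecord]:
    """Draw a full synthetic cohort, reproducibly from ``cfg.seed``.

    Per group: exactly ``n`` records; survival days per the group's
    sampling mode; each CBC value an independent truncated-normal draw;
    each value then independently blanked with probability
    ``missingness_rate``.  Records are ordered by group, then draw index,
    with ids ``S0001…``.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[PatientRecord] = []
    serial = 0
    for spec in cfg.group_specs:
        for _ in range(spec.n):
            serial += 1
            survival = _draw_survival(spec, rng)
            measurements: dict[CbcParameter, Measurement] = {}
            for param in _PARAM_ORDER:
                mean, sd = spec.per_parameter[param]
                value: float | None = _draw_value(mean, sd, cfg.value_floor, rng)
                if cfg.missingness_rate > 0 and rng.random() < cfg.missingness_rate:
                    value = None
                measurements[param] = Measurement(param, value)
            records.append(
                PatientRecord(
                    patient_id=f"S{serial:04d}",
                    survival_days=survival,
                    measurements=measurements,
                )
            )
    return records


@dataclass(frozen=True)
class EmpiricalCheckReport:
    """Outcome of checking a generated cohort against its config.

    ``count_mismatches`` maps group label → (expected n, observed n) for
    groups whose size differs from spec; ``mean_flags`` lists
    (group label, parameter) pairs whose sample mean of present values
    falls outside spec_mean ± 3·sd/√n.
    """

    count_mismatches: dict[str, tuple[int, int]]
    mean_flags: list[tuple[str, str]]

    @property
    def ok(self) -> bool:
        return not self.count_mismatches and not self.mean_flags


def empirical_check(
    cohort: Sequence[PatientRecord], cfg: SimulationConfig
) -> EmpiricalCheckReport:
    """Verify group counts exactly and per-group parameter means within a
    3·sd/√n law-of-large-numbers band around the spec means.

    Groups with spec sd = 0 or n = 0 are exempt from the mean check
    (degenerate band); truncation bias at the default floor is far
    smaller than the band width for the default specs.
    """
    by_label: dict[str, list[PatientRecord]] = {g.label: [] for g in SURVIVAL_GROUPS}
    for r in cohort:
        by_label[assign_group(r.survival_days).label].append(r)

    count_mismatches: dict[str, tuple[int, int]] = {}
    mean_flags: list[tuple[str, str]] = []
    for spec in cfg.group_specs:
        members = by_label[spec.group.label]
        if len(members) != spec.n:
            count_mismatches[spec.group.label] = (spec.n, len(members))
        if spec.n == 0:
            continue
        for param, (mean, sd) in spec.per_parameter.items():
            values = [v for r in members if (v := r.value(param)) is not None]
            if not values or sd == 0.0:
                if not values and spec.n > 0:
                    mean_flags.append((spec.group.label, param.name))
                continue
            band = 3.0 * sd / math.sqrt(len(values))
            if abs(float(np.mean(values)) - mean) > band:
                mean_flags.append((spec.group.label, param.name))
    return EmpiricalCheckReport(count_mismatches, mean_flags)
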