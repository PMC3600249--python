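"""The prognostic score: median of the signed Z-values.

Each selected CBC parameter contributes one directionally signed Z-value
(see :mod:`cbcscore.reference`); the patient's prognostic score is the
median of those Z-values.  The median — rather than a mean or weighted sum
— makes the score respond to *concerted* deviation: a single wildly
abnormal parameter cannot dominate, so the score reads as a quantitative
summary of holistic change.  In a healthy subject every Z is near zero and
the score is theoretically zero; higher scores mean greater death risk.

Worked example: Z-values 1.36 (Neu), 1.70 (Lym), 1.45 (Plt) give the score
1.45, the middle order statistic.

Missing-data policy: a record is scored over whichever selected parameters
are present, provided at least one is (``require_complete=True`` tightens
this to all-present).  Records with no present selected parameter are
*unscorable* and reported as such — never silently given a zero, since
zero is a meaningful score.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import MissingValueError, UnscorableRecordError, ValidationError
from .patients import PatientRecord
from .reference import CbcParameter, ReferenceRange, z_value

__all__ = [
    "ZVector",
    "PrognosticScore",
    "UnscorableRecord",
    "DEFAULT_SELECTED",
    "prognostic_score",
    "z_vector",
    "score_cohort",
]

#: Default scored parameter set: the three CBC parameters whose levels
#: correlate with survival time in critically ill cohorts.
DEFAULT_SELECTED: frozenset[CbcParameter] = frozenset(
    {CbcParameter.NEU, CbcParameter.LYM, CbcParameter.PLT}
)


@dataclass(frozen=True)
class ZVector:
    """Per-patient signed Z-values for some subset of the CBC parameters.

    ``provenance`` identifies the source patient record.  All entries must
    be finite and at least one must be present.
    """

    entries: Mapping[CbcParameter, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(
                f"ZVector for {self.provenance!r} has no entries"
            )
        for p, z in self.entries.items():
            if not (z == z and abs(z) != float("inf")):
                raise ValidationError(
                    f"ZVector for {self.provenance!r}: non-finite Z for {p.name}"
                )


@dataclass(frozen=True)
class PrognosticScore:
    """A patient's prognostic score and exactly which Z-values produced it."""

    value: float
    n_parameters_used: int
    parameters_used: frozenset[CbcParameter]
    provenance: str = ""


@dataclass(frozen=True)
class UnscorableRecord:
    """A record that could not be scored, with the reason why."""

    patient_id: str
    reason: str


def prognostic_score(
    z: ZVector, selected: Iterable[CbcParameter]
) -> PrognosticScore:
    """Median of the Z-values over ``selected ∩ present`` parameters.

    For an even number of contributing parameters the median is the
    arithmetic mean of the two central order statistics.

    Raises
    ------
    UnscorableRecordError
        If no selected parameter is present in the Z-vector.
    """
    selected = frozenset(selected)
    used = selected & frozenset(z.entries)
    if not used:
        raise UnscorableRecordError(
            f"record {z.provenance!r}: none of the selected parameters "
            f"({', '.join(sorted(p.name for p in selected))}) has a Z-value"
        )
    value = statistics.median(z.entries[p] for p in used)
    return PrognosticScore(
        value=float(value),
        n_parameters_used=len(used),
        parameters_used=used,
        provenance=z.provenance,
    )


def z_vector(
    record: PatientRecord,
    panel: Mapping[CbcParameter, ReferenceRange],
    parameters: Iterable[CbcParameter] | None = None,
) -> ZVector:
    """Standardize a record's present measurements into a :class:`ZVector`.

    Only parameters with a present value (and, if ``parameters`` is given,
    within that subset) contribute.  Raises :class:`UnscorableRecordError`
    if nothing is present.
    """
    wanted = frozenset(parameters) if parameters is not None else None
    entries: dict[CbcParameter, float] = {}
    for param, m in record.measurements.items():
        if m.is_missing or (wanted is not None and param not in wanted):
            continue
        ref = panel.get(param)
        if ref is None:
            raise ValidationError(
                f"reference panel lacks {param.name}, required by patient "
                f"{record.patient_id!r}"
            )
        entries[param] = z_value(m, ref)
    if not entries:
        raise UnscorableRecordError(
            f"record {record.patient_id!r}: no present measurements to standardize"
        )
    return ZVector(entries=entries, provenance=record.patient_id)


def score_cohort(
    records: Sequence[PatientRecord],
    panel: Mapping[CbcParameter, ReferenceRange],
    selected: Iterable[CbcParameter] = DEFAULT_SELECTED,
    *,
    require_complete: bool = False,
) -> tuple[list[PrognosticScore], list[UnscorableRecord]]:
    """Score every record in a cohort.

    Returns ``(scores, unscorable)``: one :class:`PrognosticScore` per
    scorable record in input order, and one :class:`UnscorableRecord` per
    record that could not be scored (no selected parameter present, or —
    with ``require_complete=True`` — any selected parameter absent).
    An empty input yields two empty lists.
    """
    selected = frozenset(selected)
    missing_refs = selected - set(panel)
    if missing_refs:
        raise ValidationError(
            "reference panel does not cover selected parameters: "
            + ", ".join(sorted(p.name for p in missing_refs))
        )
    scores: list[PrognosticScore] = []
    unscorable: list[UnscorableRecord] = []
    for record in records:
        present = record.present_parameters() & selected
        if not present:
            unscorable.append(
                UnscorableRecord(
                    record.patient_id,
                    "no selected parameter has a present value",
                )
            )
            continue
        if require_complete and present != selected:
            absent = ", ".join(sorted(p.name for p in selected - present))
            unscorable.append(
                UnscorableRecord(
                    record.patient_id,
                    f"require_complete: missing {absent}",
                )
            )
            continue
        zv = z_vector(record, panel, parameters=present)
        scores.append(prognostic_score(zv, present))
    return scores, unscorable
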