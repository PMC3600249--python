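"""Per-patient records: survival time plus the five CBC measurements."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError
from .reference import CbcParameter, Measurement

__all__ = ["PatientRecord", "STUDY_MAX_SURVIVAL_DAYS"]

#: Inclusion window: every study subject died within one year of sampling.
STUDY_MAX_SURVIVAL_DAYS = 365


@dataclass(frozen=True)
class PatientRecord:
    """One critically ill patient: survival time from CBC sampling to
    death, in whole days, and the CBC measurements taken at sampling.

    ``survival_days`` must lie in [1, 365]: the cohort design includes only
    patients who died within a year of the blood draw, and death on the day
    of sampling is recorded as day 1.  Any of the five measurements may be
    missing.  ``diagnosis`` is free text carried for provenance only; no
    computation reads it.
    """

    patient_id: str
    survival_days: int
    measurements: Mapping[CbcParameter, Measurement] = field(default_factory=dict)
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= int(self.survival_days) <= STUDY_MAX_SURVIVAL_DAYS):
            raise ValidationError(
                f"patient {self.patient_id!r}: survival_days must be in "
                f"[1, {STUDY_MAX_SURVIVAL_DAYS}], got {self.survival_days!r}"
            )
        for param, m in self.measurements.items():
            if m.parameter is not param:
                raise ValidationError(
                    f"patient {self.patient_id!r}: measurement keyed "
                    f"{param.name} describes {m.parameter.name}"
                )

    def value(self, param: CbcParameter) -> float | None:
        """The measured value for ``param``, or None if absent/missing."""
        m = self.measurements.get(param)
        return None if m is None else m.value

    def present_parameters(self) -> set[CbcParameter]:
        return {p for p, m in self.measurements.items() if not m.is_missing}
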