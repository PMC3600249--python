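"""CBC parameters, laboratory reference ranges, and directional Z-values.

A complete blood cell count (CBC) measurement is standardized against a
healthy-population reference range (mean ``X̄``, standard deviation ``S``)
into a Z-value signed so that the clinically adverse direction is positive:

* neutrophils (Neu) and lymphocytes (Lym) rise in acute illness, so
  ``Z = (X − X̄) / S`` (high is risk);
* red cells (RBC), hemoglobin (HB) and platelets (Plt) fall, so
  ``Z = (X̄ − X) / S`` (low is risk).

A healthy subject therefore has every Z near zero, and larger Z means a
larger departure in the direction associated with death risk.  The risk
direction is a property of the :class:`ReferenceRange`, not of the formula,
so panels for other laboratories or parameter sets can reuse the machinery;
the bundled default panel pins the adult reference values and directions
used throughout this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import MissingValueError, ParameterMismatchError, ValidationError

__all__ = [
    "CbcParameter",
    "Direction",
    "ReferenceRange",
    "Measurement",
    "z_value",
    "default_reference_panel",
    "load_panel",
    "save_panel",
]


class CbcParameter(enum.Enum):
    """The five CBC parameters used by the prognostic score."""

    NEU = "neu"
    LYM = "lym"
    RBC = "rbc"
    HB = "hb"
    PLT = "plt"

    @property
    def display_unit(self) -> str:
        return _UNITS[self]

    def __repr__(self) -> str:  # terse reprs keep summaries readable
        return self.name


_UNITS: dict[CbcParameter, str] = {
    CbcParameter.NEU: "10^9/L",
    CbcParameter.LYM: "10^9/L",
    CbcParameter.RBC: "10^12/L",
    CbcParameter.HB: "g/L",
    CbcParameter.PLT: "10^9/L",
}


class Direction(enum.Enum):
    """Which side of the reference mean carries death risk."""

    HIGH_IS_RISK = "high_is_risk"
    LOW_IS_RISK = "low_is_risk"


@dataclass(frozen=True)
class ReferenceRange:
    """Healthy-population mean and SD of one CBC parameter, plus the risk
    direction used to sign its Z-value.

    Parameters
    ----------
    parameter : CbcParameter
    mean : float
        Reference mean X̄, in the parameter's display unit; must be > 0.
    sd : float
        Reference standard deviation S; must be > 0.
    direction : Direction
        ``HIGH_IS_RISK`` → Z = (X − X̄)/S; ``LOW_IS_RISK`` → Z = (X̄ − X)/S.
    """

    parameter: CbcParameter
    mean: float
    sd: float
    direction: Direction

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValidationError(
                f"reference mean must be positive, got {self.mean!r} "
                f"for {self.parameter.name}"
            )
        if not self.sd > 0:
            raise ValidationError(
                f"reference sd must be positive, got {self.sd!r} "
                f"for {self.parameter.name}"
            )


@dataclass(frozen=True)
class Measurement:
    """One measured CBC value; ``value=None`` encodes a missing result."""

    parameter: CbcParameter
    value: float | None

    def __post_init__(self) -> None:
        if self.value is not None and self.value < 0:
            raise ValidationError(
                f"{self.parameter.name} measurement must be >= 0, "
                f"got {self.value!r}"
            )

    @property
    def is_missing(self) -> bool:
        return self.value is None


def z_value(m: Measurement, ref: ReferenceRange) -> float:
    """Directionally signed Z-value of a measurement against its reference.

    Returns ``(X − X̄)/S`` when the range's direction is ``HIGH_IS_RISK``
    and ``(X̄ − X)/S`` when ``LOW_IS_RISK``, so that positive Z always means
    deviation toward higher death risk.

    Raises
    ------
    ParameterMismatchError
        If the measurement and reference describe different parameters.
    MissingValueError
        If the measurement value is absent; callers filter missing values
        before standardization.
    """
    if m.parameter is not ref.parameter:
        raise ParameterMismatchError(
            f"measurement is {m.parameter.name}, reference is "
            f"{ref.parameter.name}"
        )
    if m.value is None:
        raise MissingValueError(
            f"{m.parameter.name} value is missing; cannot standardize"
        )
    if ref.direction is Direction.HIGH_IS_RISK:
        return (m.value - ref.mean) / ref.sd
    return (ref.mean - m.value) / ref.sd


# Adult reference panel used throughout: counts in 10^9/L (RBC 10^12/L,
# HB g/L).  Directions: Neu/Lym elevated in critical illness, RBC/HB/Plt
# depressed.
_DEFAULT_PANEL_SPEC: tuple[tuple[CbcParameter, float, float, Direction], ...] = (
    (CbcParameter.NEU, 3.5, 1.2, Direction.HIGH_IS_RISK),
    (CbcParameter.LYM, 2.2, 0.6, Direction.HIGH_IS_RISK),
    (CbcParameter.RBC, 4.5, 0.6, Direction.LOW_IS_RISK),
    (CbcParameter.HB, 142.0, 20.0, Direction.LOW_IS_RISK),
    (CbcParameter.PLT, 210.0, 53.0, Direction.LOW_IS_RISK),
)


def default_reference_panel() -> dict[CbcParameter, ReferenceRange]:
    """The bundled adult CBC reference panel.

    Returns a mapping from each of the five parameters to its
    :class:`ReferenceRange`:

    ========= ========== ====== ==============
    parameter mean       sd     direction
    ========= ========== ====== ==============
    NEU       3.5        1.2    HIGH_IS_RISK
    LYM       2.2        0.6    HIGH_IS_RISK
    RBC       4.5        0.6    LOW_IS_RISK
    HB        142        20     LOW_IS_RISK
    PLT       210        53     LOW_IS_RISK
    ========= ========== ====== ==============
    """
    return {
        p: ReferenceRange(p, mean, sd, direction)
        for p, mean, sd, direction in _DEFAULT_PANEL_SPEC
    }


def save_panel(panel: Mapping[CbcParameter, ReferenceRange], path: str | Path) -> None:
    """Serialize a reference panel to a YAML config file."""
    doc = {
        ref.parameter.value: {
            "mean": float(ref.mean),
            "sd": float(ref.sd),
            "direction": ref.direction.value,
        }
        for ref in panel.values()
    }
    Path(path).write_text(yaml.safe_dump({"reference_panel": doc}, sort_keys=False))


def load_panel(path: str | Path) -> dict[CbcParameter, ReferenceRange]:
    """Load a reference panel from a YAML config file written by
    :func:`save_panel` (or hand-edited in the same layout)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "reference_panel" not in raw:
        raise ValidationError(f"{path}: missing top-level 'reference_panel' key")
    panel: dict[CbcParameter, ReferenceRange] = {}
    for code, fields in raw["reference_panel"].items():
        try:
            param = CbcParameter(code)
        except ValueError as exc:
            raise ValidationError(f"{path}: unknown parameter code {code!r}") from exc
        try:
            panel[param] = ReferenceRange(
                param,
                float(fields["mean"]),
                float(fields["sd"]),
                Direction(fields["direction"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad entry for {code!r}: {exc}") from exc
    return panel
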