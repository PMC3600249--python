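"""CSV input/output and the end-to-end pipeline driver.

Patient tables are plain CSV with header
``patient_id,survival_days,neu,lym,rbc,hb,plt`` (an optional ``diagnosis``
column is carried through untouched).  Units are fixed: counts in 10^9/L,
RBC in 10^12/L, HB in g/L.  An empty cell is a missing measurement;
malformed rows are collected into a row-level error report with line
numbers rather than aborting the read.

:func:`run_pipeline` chains the stages — optional Spearman predictor
selection, per-patient scoring, survival-group summaries — and writes
four artifacts: a selection report, per-patient scores, a group CBC
summary, and score quartiles by group, plus a run log sufficient to
reproduce the outputs (seed, config, alpha, panel, counts).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CbcScoreError, ValidationError
from .groups import GroupSummary, summarize_groups
from .patients import PatientRecord
from .reference import (
    CbcParameter,
    Measurement,
    ReferenceRange,
    default_reference_panel,
)
from .scoring import (
    DEFAULT_SELECTED,
    PrognosticScore,
    UnscorableRecord,
    score_cohort,
)
from .selection import CorrelationResult, SelectionConfig, select_predictors

__all__ = [
    "PatientTable",
    "RowError",
    "read_patients",
    "write_patients",
    "write_scores",
    "write_selection",
    "write_group_summary",
    "write_score_quartiles",
    "PipelineResult",
    "run_pipeline",
]

_COLUMNS = ["patient_id", "survival_days", "neu", "lym", "rbc", "hb", "plt"]
_PARAM_COLUMNS = {
    CbcParameter.NEU: "neu",
    CbcParameter.LYM: "lym",
    CbcParameter.RBC: "rbc",
    CbcParameter.HB: "hb",
    CbcParameter.PLT: "plt",
}


@dataclass(frozen=True)
class RowError:
    """One rejected input row: 1-based line number (header = line 1) and
    the reason for rejection."""

    line: int
    message: str


@dataclass(frozen=True)
class PatientTable:
    """A validated set of patient records plus any row-level errors."""

    rows: tuple[PatientRecord, ...]
    source: str
    errors: tuple[RowError, ...] = ()


def _parse_cell(raw: object) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    return float(text)  # ValueError propagates to row handler


def read_patients(path: str | Path) -> PatientTable:
    """Read and validate a patient CSV.

    Missing required columns are fatal (:class:`ValidationError`); bad
    rows — unparseable numbers, negative values, survival time outside
    [1, 365], duplicate ids — are reported per row and excluded.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required columns: {', '.join(missing)}"
        )
    has_diagnosis = "diagnosis" in df.columns

    records: list[PatientRecord] = []
    errors: list[RowError] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rowmap = dict(zip(df.columns, row))
        pid = str(rowmap["patient_id"]).strip()
        try:
            if not pid:
                raise ValidationError("empty patient_id")
            if pid in seen_ids:
                raise ValidationError(f"duplicate patient_id {pid!r}")
            survival = int(str(rowmap["survival_days"]).strip())
            measurements = {
                param: Measurement(param, _parse_cell(rowmap[col]))
                for param, col in _PARAM_COLUMNS.items()
            }
            diagnosis = (
                str(rowmap["diagnosis"]).strip() or None if has_diagnosis else None
            )
            records.append(
                PatientRecord(
                    patient_id=pid,
                    survival_days=survival,
                    measurements=measurements,
                    diagnosis=diagnosis,
                )
            )
            seen_ids.add(pid)
        except (ValueError, CbcScoreError) as exc:
            errors.append(RowError(line, str(exc)))
    return PatientTable(tuple(records), str(path), tuple(errors))


def write_patients(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records in the same CSV layout :func:`read_patients` accepts.

    Round-trip safe: values and missingness (empty cells) are preserved.
    """
    rows = []
    any_diagnosis = any(r.diagnosis for r in records)
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "survival_days": r.survival_days,
        }
        for param, col in _PARAM_COLUMNS.items():
            v = r.value(param)
            row[col] = "" if v is None else repr(v)
        if any_diagnosis:
            row["diagnosis"] = r.diagnosis or ""
        rows.append(row)
    cols = _COLUMNS + (["diagnosis"] if any_diagnosis else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_scores(
    scores: Sequence[PrognosticScore],
    unscorable: Sequence[UnscorableRecord],
    path: str | Path,
) -> None:
    """Per-patient score CSV: patient_id, score, n_parameters_used,
    parameters_used (semicolon-joined codes).  Unscorable records appear
    with an empty score and the reason."""
    rows = []
    for s in scores:
        codes = ";".join(sorted(p.value for p in s.parameters_used))
        rows.append(
            {
                "patient_id": s.provenance,
                "score": f"{s.value:.6g}",
                "n_parameters_used": s.n_parameters_used,
                "parameters_used": codes,
                "note": "",
            }
        )
    for u in unscorable:
        rows.append(
            {
                "patient_id": u.patient_id,
                "score": "",
                "n_parameters_used": 0,
                "parameters_used": "",
                "note": u.reason,
            }
        )
    pd.DataFrame(
        rows,
        columns=["patient_id", "score", "n_parameters_used", "parameters_used", "note"],
    ).to_csv(path, index=False)


def write_selection(
    results: Sequence[CorrelationResult], path: str | Path
) -> None:
    """Selection report CSV: parameter, rho, p, n, selected, testable."""
    rows = [
        {
            "parameter": r.parameter.value,
            "rho": "" if math.isnan(r.rho) else f"{r.rho:.6g}",
            "p": "" if math.isnan(r.p_value) else f"{r.p_value:.6g}",
            "n": r.n,
            "selected": r.selected,
            "testable": r.testable,
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["parameter", "rho", "p", "n", "selected", "testable"]
    ).to_csv(path, index=False)


def _fmt(x: float) -> str:
    return "" if (isinstance(x, float) and math.isnan(x)) else f"{x:.6g}"


def write_group_summary(
    summaries: Sequence[GroupSummary], path: str | Path
) -> None:
    """Group CBC summary CSV: one row per survival group with n, median
    survival day and mean/sd per parameter."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "group": s.group.label,
            "survival_median_day": _fmt(s.survival_median),
            "n": s.n,
        }
        for param in CbcParameter:
            mean, sd = s.per_parameter[param]
            row[f"{param.value}_mean"] = _fmt(mean)
            row[f"{param.value}_sd"] = _fmt(sd)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_score_quartiles(
    summaries: Sequence[GroupSummary], path: str | Path
) -> None:
    """Score-distribution CSV: group, q25, q50, q75 (empty when no record
    in the group is scorable)."""
    rows = []
    for s in summaries:
        q = s.score_quartiles
        rows.append(
            {
                "group": s.group.label,
                "q25": _fmt(q[0]) if q else "",
                "q50": _fmt(q[1]) if q else "",
                "q75": _fmt(q[2]) if q else "",
            }
        )
    pd.DataFrame(rows, columns=["group", "q25", "q50", "q75"]).to_csv(
        path, index=False
    )


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produced, plus the output paths."""

    selection: tuple[CorrelationResult, ...]
    selected_parameters: frozenset[CbcParameter]
    scores: tuple[PrognosticScore, ...]
    unscorable: tuple[UnscorableRecord, ...]
    summaries: tuple[GroupSummary, ...]
    outputs: dict[str, str] = field(default_factory=dict)


def run_pipeline(
    records: Sequence[PatientRecord],
    out_dir: str | Path,
    *,
    panel: Mapping[CbcParameter, ReferenceRange] | None = None,
    select_auto: bool = False,
    parameters: Iterable[CbcParameter] = DEFAULT_SELECTED,
    alpha: float = 0.05,
    require_complete: bool = False,
    seed: int | None = None,
    config_note: str = "",
) -> PipelineResult:
    """Run selection (always reported), scoring and grouping; write the
    four CSV artifacts and a JSON run log into ``out_dir``.

    With ``select_auto=True`` the scored parameter set is taken from the
    Spearman selection (p < alpha) on this cohort; otherwise
    ``parameters`` is used.  Raises :class:`ValidationError` if no record
    is scorable, with diagnostic counts in the message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = default_reference_panel() if panel is None else dict(panel)

    selection = tuple(select_predictors(records, SelectionConfig(alpha=alpha)))
    if select_auto:
        selected = frozenset(r.parameter for r in selection if r.selected)
        if not selected:
            raise ValidationError(
                "automatic selection chose no parameter "
                f"(alpha={alpha}, n={len(records)}); specify parameters explicitly"
            )
    else:
        selected = frozenset(parameters)

    scores, unscorable = score_cohort(
        records, panel, selected, require_complete=require_complete
    )
    if records and not scores:
        raise ValidationError(
            f"no scorable record: {len(records)} read, "
            f"{len(unscorable)} unscorable"
        )
    summaries = tuple(
        summarize_groups(
            records, panel, selected, require_complete=require_complete
        )
    )

    paths = {
        "selection": out_dir / "selection.csv",
        "scores": out_dir / "scores.csv",
        "group_summary": out_dir / "group_summary.csv",
        "score_quartiles": out_dir / "score_quartiles.csv",
        "run_log": out_dir / "run_log.json",
    }
    write_selection(selection, paths["selection"])
    write_scores(scores, unscorable, paths["scores"])
    write_group_summary(summaries, paths["group_summary"])
    write_score_quartiles(summaries, paths["score_quartiles"])

    log = {
        "seed": seed,
        "alpha": alpha,
        "select_auto": select_auto,
        "selected_parameters": sorted(p.value for p in selected),
        "require_complete": require_complete,
        "reference_panel": {
            ref.parameter.value: {
                "mean": ref.mean,
                "sd": ref.sd,
                "direction": ref.direction.value,
            }
            for ref in panel.values()
        },
        "counts": {
            "records": len(records),
            "scored": len(scores),
            "unscorable": len(unscorable),
        },
        "config_note": config_note,
    }
    paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        selection=selection,
        selected_parameters=selected,
        scores=tuple(scores),
        unscorable=tuple(unscorable),
        summaries=summaries,
        outputs={k: str(v) for k, v in paths.items()},
    )
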