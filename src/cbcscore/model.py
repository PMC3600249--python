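"""Model/Results facade over the prognostic-scoring pipeline.

``CbcPrognosisModel`` holds a cohort and a reference panel;
``fit()`` runs the Spearman predictor-selection step and the scoring
pipeline, returning a ``CbcPrognosisResults`` that carries the
correlation table, the selected parameter set, per-patient scores,
survival-group summaries and a printable ``summary()``.

This mirrors the model/results split used by mainstream statistical
packages: the model is immutable configuration + data, the results object
is everything estimated from them.

Example
-------
>>> from cbcscore import CbcPrognosisModel, generate_cohort, SimulationConfig
>>> cohort = generate_cohort(SimulationConfig(seed=7))
>>> res = CbcPrognosisModel(cohort).fit(select="auto")
>>> sorted(p.name for p in res.selected_parameters)   # doctest: +SKIP
['LYM', 'NEU', 'PLT']
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .groups import GroupSummary, summarize_groups
from .io import PatientTable
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

__all__ = ["CbcPrognosisModel", "CbcPrognosisResults"]

_COLUMN_TO_PARAM = {p.value: p for p in CbcParameter}


class CbcPrognosisModel:
    """CBC-based prognostic scoring model for a cohort of critically ill
    patients.

    Parameters
    ----------
    records : sequence of PatientRecord, or PatientTable
        The cohort: survival time (days to death) plus CBC measurements.
    panel : mapping CbcParameter -> ReferenceRange, optional
        Reference ranges used for Z-standardization; defaults to the
        bundled adult panel.
    alpha : float
        Two-tailed significance level for predictor selection.
    """

    def __init__(
        self,
        records: Sequence[PatientRecord] | PatientTable,
        panel: Mapping[CbcParameter, ReferenceRange] | None = None,
        alpha: float = 0.05,
    ) -> None:
        if isinstance(records, PatientTable):
            records = records.rows
        self.records: tuple[PatientRecord, ...] = tuple(records)
        self.panel = default_reference_panel() if panel is None else dict(panel)
        self.alpha = float(alpha)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        panel: Mapping[CbcParameter, ReferenceRange] | None = None,
        alpha: float = 0.05,
    ) -> "CbcPrognosisModel":
        """Build a model from a DataFrame with columns ``patient_id``,
        ``survival_days`` and any of ``neu, lym, rbc, hb, plt``
        (NaN = missing)."""
        required = {"patient_id", "survival_days"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"DataFrame lacks columns: {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            rowmap = row._asdict()
            measurements = {}
            for col, param in _COLUMN_TO_PARAM.items():
                if col not in df.columns:
                    continue
                raw = rowmap[col]
                value = None if raw is None or (
                    isinstance(raw, float) and math.isnan(raw)
                ) else float(raw)
                measurements[param] = Measurement(param, value)
            records.append(
                PatientRecord(
                    patient_id=str(rowmap["patient_id"]),
                    survival_days=int(rowmap["survival_days"]),
                    measurements=measurements,
                )
            )
        return cls(records, panel=panel, alpha=alpha)

    def fit(
        self,
        select: str = "fixed",
        parameters: Iterable[CbcParameter] = DEFAULT_SELECTED,
        require_complete: bool = False,
    ) -> "CbcPrognosisResults":
        """Run selection and scoring.

        ``select="fixed"`` scores the given ``parameters`` (default
        NEU, LYM, PLT); ``select="auto"`` re-runs the Spearman selection on
        this cohort and scores the parameters with p < alpha.
        """
        if select not in ("fixed", "auto"):
            raise ValueError(f"select must be 'fixed' or 'auto', got {select!r}")
        correlations = tuple(
            select_predictors(self.records, SelectionConfig(alpha=self.alpha))
        )
        if select == "auto":
            chosen = frozenset(r.parameter for r in correlations if r.selected)
            if not chosen:
                raise ValidationError(
                    f"automatic selection chose no parameter at alpha={self.alpha}"
                )
        else:
            chosen = frozenset(parameters)
        scores, unscorable = score_cohort(
            self.records, self.panel, chosen, require_complete=require_complete
        )
        summaries = tuple(
            summarize_groups(
                self.records, self.panel, chosen,
                require_complete=require_complete,
            )
        )
        return CbcPrognosisResults(
            model=self,
            correlations=correlations,
            selected_parameters=chosen,
            scores=tuple(scores),
            unscorable=tuple(unscorable),
            summaries=summaries,
        )


@dataclass(frozen=True)
class CbcPrognosisResults:
    """Fitted results: correlation table, selected predictors, per-patient
    prognostic scores and survival-group summaries."""

    model: CbcPrognosisModel
    correlations: tuple[CorrelationResult, ...]
    selected_parameters: frozenset[CbcParameter]
    scores: tuple[PrognosticScore, ...]
    unscorable: tuple[UnscorableRecord, ...]
    summaries: tuple[GroupSummary, ...]

    @property
    def correlation_table(self) -> pd.DataFrame:
        """Spearman rho/p per CBC parameter vs survival time."""
        return pd.DataFrame(
            [
                {
                    "parameter": r.parameter.name,
                    "rho": r.rho,
                    "p": r.p_value,
                    "n": r.n,
                    "selected": r.selected,
                    "testable": r.testable,
                }
                for r in self.correlations
            ]
        ).set_index("parameter")

    @property
    def score_frame(self) -> pd.DataFrame:
        """Per-patient scores as a DataFrame indexed by patient_id."""
        return pd.DataFrame(
            [
                {
                    "patient_id": s.provenance,
                    "score": s.value,
                    "n_parameters_used": s.n_parameters_used,
                }
                for s in self.scores
            ]
        ).set_index("patient_id")

    @property
    def group_table(self) -> pd.DataFrame:
        """Per-group n, median survival day and score quartiles."""
        rows = []
        for s in self.summaries:
            q = s.score_quartiles or (math.nan, math.nan, math.nan)
            rows.append(
                {
                    "group": s.group.label,
                    "n": s.n,
                    "survival_median_day": s.survival_median,
                    "q25": q[0],
                    "q50": q[1],
                    "q75": q[2],
                }
            )
        return pd.DataFrame(rows).set_index("group")

    def summary(self) -> str:
        """Printable report: selection table, selected set, group quartiles."""
        lines = [
            "CBC Prognostic Score".center(58),
            "=" * 58,
            f"Records: {len(self.model.records)}   scored: {len(self.scores)}"
            f"   unscorable: {len(self.unscorable)}",
            f"Alpha: {self.model.alpha}   selected: "
            + (", ".join(sorted(p.name for p in self.selected_parameters)) or "-"),
            "-" * 58,
            "Spearman correlation with survival time (days)",
            f"{'parameter':<10}{'rho':>10}{'p':>12}{'n':>7}  selected",
        ]
        for r in self.correlations:
            rho = "   nan" if math.isnan(r.rho) else f"{r.rho:10.3f}"
            p = "    nan" if math.isnan(r.p_value) else f"{r.p_value:12.4g}"
            mark = "*" if r.selected else ("!" if not r.testable else "")
            lines.append(f"{r.parameter.name:<10}{rho}{p}{r.n:>7}  {mark}")
        lines += [
            "-" * 58,
            "Prognostic score quartiles by survival group",
            f"{'group':<14}{'n':>5}{'q25':>9}{'q50':>9}{'q75':>9}",
        ]
        for s in self.summaries:
            if s.score_quartiles:
                q25, q50, q75 = (f"{v:9.2f}" for v in s.score_quartiles)
            else:
                q25 = q50 = q75 = "        -"
            lines.append(f"{s.group.label:<14}{s.n:>5}{q25}{q50}{q75}")
        lines.append("=" * 58)
        return "\n".join(lines)
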