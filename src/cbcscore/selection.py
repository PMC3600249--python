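"""Predictor selection by Spearman rank correlation against survival time.

Each CBC parameter is tested for monotone association with survival time
(days from sampling to death) using Spearman's rho with midrank tie
handling, two-tailed, at a configurable significance level (default
α = 0.05).  Parameters with p < α are flagged as selected predictors.

Rank correlation is deliberate here: it is invariant to any strictly
monotone transform of survival time, so whether time is analysed raw or
log-transformed is immaterial.

Two p-value routes are provided: the usual t-approximation
``t = ρ·sqrt((n−2)/(1−ρ²))`` on n−2 degrees of freedom (excellent at
cohort sizes of hundreds), and exact permutation enumeration for small n
(≤ 10), which serves as an independent check of the approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientSampleError, UndefinedCorrelationError
from .patients import PatientRecord
from .reference import CbcParameter

__all__ = [
    "CorrelationResult",
    "SelectionConfig",
    "spearman_rho",
    "spearman_p_two_tailed",
    "spearman_p_exact",
    "select_predictors",
]

#: Minimum complete pairs for a testable correlation.
MIN_PAIRS = 4


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for the predictor-selection step.

    ``alpha`` is the two-tailed significance level; the test is always
    two-tailed (an adverse CBC shift may correlate with survival in either
    direction a priori).
    """

    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman test of one CBC parameter against survival time.

    ``testable`` is False when fewer than four complete (survival, value)
    pairs exist or the correlation is undefined; such parameters carry
    NaN rho/p and are never selected.
    """

    parameter: CbcParameter
    rho: float
    p_value: float
    n: int
    selected: bool
    testable: bool = True


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with midrank (average) tie handling.

    Computed as the Pearson correlation of the two midrank vectors.

    Raises
    ------
    UndefinedCorrelationError
        If either vector has zero rank variance (all values tied).
    ValueError
        On length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError(
            "all values tied in one vector; rank correlation undefined"
        )
    rho = float(np.corrcoef(rx, ry)[0, 1])
    # guard against floating drift outside [-1, 1]
    return max(-1.0, min(1.0, rho))


def spearman_p_two_tailed(rho: float, n: int) -> float:
    """Two-tailed p for Spearman's rho via the t-approximation.

    Refers ``t = ρ·sqrt((n−2)/(1−ρ²))`` to Student's t with n−2 degrees of
    freedom.  By convention |ρ| = 1 returns p = 0 (the statistic diverges).

    Raises
    ------
    InsufficientSampleError
        If n < 4.
    """
    if n < MIN_PAIRS:
        raise InsufficientSampleError(f"t-approximation needs n >= 4, got {n}")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho!r}")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_p_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-tailed permutation p-value for Spearman's rho.

    Enumerates all n! orderings of ``y`` and returns the fraction whose
    |rho| is at least the observed |rho| (within numerical tolerance).
    Intended for n ≤ 10; the factorial cost is prohibitive beyond that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 10:
        raise ValueError(f"exact enumeration limited to n <= 10, got {n}")
    observed = abs(spearman_rho(x, y))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rp = ry[list(perm)]
        rho = float(np.mean(rx * (rp - rp.mean()) / rp.std()))
        if abs(rho) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def select_predictors(
    records: Sequence[PatientRecord],
    cfg: SelectionConfig = SelectionConfig(),
) -> list[CorrelationResult]:
    """Test every CBC parameter against survival time; flag predictors.

    For each parameter, complete (survival_days, value) pairs are formed
    by pairwise deletion of missing values; Spearman's rho and the
    two-tailed t-approximation p are computed; ``selected`` is set by
    ``p < cfg.alpha``.  Parameters with fewer than four complete pairs, or
    whose correlation is undefined (zero rank variance), are returned with
    ``testable=False`` and are never selected.

    Results are returned in the canonical parameter order
    (NEU, LYM, RBC, HB, PLT).
    """
    results: list[CorrelationResult] = []
    for param in CbcParameter:
        pairs = [
            (float(r.survival_days), v)
            for r in records
            if (v := r.value(param)) is not None
        ]
        n = len(pairs)
        if n < MIN_PAIRS:
            results.append(
                CorrelationResult(param, math.nan, math.nan, n, False, testable=False)
            )
            continue
        surv, vals = zip(*pairs)
        try:
            rho = spearman_rho(surv, vals)
        except UndefinedCorrelationError:
            results.append(
                CorrelationResult(param, math.nan, math.nan, n, False, testable=False)
            )
            continue
        p = spearman_p_two_tailed(rho, n)
        results.append(
            CorrelationResult(param, rho, p, n, selected=bool(p < cfg.alpha))
        )
    return results
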