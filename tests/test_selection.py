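"""Spearman rank correlation and predictor selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cbcscore import (
    CbcParameter,
    InsufficientSampleError,
    SelectionConfig,
    UndefinedCorrelationError,
    select_predictors,
    spearman_p_exact,
    spearman_p_two_tailed,
    spearman_rho,
)
from scipy import stats

from conftest import make_record

P = CbcParameter


def footrule_rho(x, y):
    """Independent oracle: 1 - 6*sum(d^2)/(n(n^2-1)) on untied data."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    d = rx - ry
    return 1 - 6 * float(d @ d) / (n * (n * n - 1))


class TestSpearmanRho:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4), (10, 20, 30, 40), 1.0),
            ((1, 2, 3, 4), (8, 6, 4, 2), -1.0),
            ((1, 2, 3, 4, 5), (2, 1, 4, 3, 5), 0.8),  # 1 - 24/120
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_midrank_tie_handling(self):
        # x ranks with midranks: (1.5, 1.5, 3); rank-Pearson by hand
        x, y = (1, 1, 2), (1, 2, 3)
        rx = np.array([1.5, 1.5, 3.0])
        ry = np.array([1.0, 2.0, 3.0])
        expected = float(np.corrcoef(rx, ry)[0, 1])
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho((1, 1, 1, 1), (1, 2, 3, 4))

    def test_too_short_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho((1, 2), (3, 4))
        with pytest.raises(ValueError):
            spearman_rho((1, 2, 3), (1, 2))

    def test_symmetry(self):
        x, y = (3, 1, 4, 1, 5, 9, 2, 6), (2, 7, 1, 8, 2, 8, 1, 8)
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x), abs=1e-12)

    @given(
        y=st.permutations(list(range(1, 7))),
        exponent=st.sampled_from([1.0, 0.5, 3.0]),
    )
    def test_invariant_under_strictly_monotone_transform(self, y, exponent):
        x = list(range(1, 7))
        transformed = [v**exponent for v in y]
        assert spearman_rho(x, y) == pytest.approx(
            spearman_rho(x, transformed), abs=1e-12
        )

    def test_matches_closed_form_on_all_n6_permutations(self):
        """All 720 untied orderings agree with 1 - 6*sum(d^2)/(n(n^2-1))."""
        x = list(range(1, 7))
        for y in itertools.permutations(x):
            assert spearman_rho(x, y) == pytest.approx(
                footrule_rho(x, y), abs=1e-12
            )


class TestSpearmanP:
    def test_null_rho_gives_p_one(self):
        assert spearman_p_two_tailed(0.0, 10) == pytest.approx(1.0)

    def test_perfect_correlation_gives_p_zero_by_convention(self):
        assert spearman_p_two_tailed(1.0, 8) == 0.0
        assert spearman_p_two_tailed(-1.0, 8) == 0.0

    def test_p_decreases_toward_zero_as_rho_grows(self):
        ps = [spearman_p_two_tailed(r, 20) for r in (0.1, 0.4, 0.7, 0.95, 0.999)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-5

    def test_known_t_tail_value(self):
        # rho=0.8, n=5 -> t = 0.8*sqrt(3/0.36), df=3; independent t CDF
        t = 0.8 * math.sqrt(3 / 0.36)
        expected = 2 * stats.t.sf(t, df=3)
        assert spearman_p_two_tailed(0.8, 5) == pytest.approx(expected, rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientSampleError):
            spearman_p_two_tailed(0.5, 3)

    def test_t_approximation_close_to_exact_permutation_p(self):
        """The documented accuracy of the t-approximation against exact
        enumeration: within 0.10 absolute for 5 <= n <= 8."""
        cases = [
            ((1, 2, 3, 4, 5), (2, 1, 4, 3, 5)),
            ((1, 2, 3, 4, 5, 6), (2, 1, 4, 3, 6, 5)),
            ((1, 2, 3, 4, 5, 6, 7), (1, 3, 2, 5, 4, 7, 6)),
            ((1, 2, 3, 4, 5, 6, 7), (7, 5, 6, 3, 4, 1, 2)),
        ]
        for x, y in cases:
            exact = spearman_p_exact(x, y)
            approx = spearman_p_two_tailed(spearman_rho(x, y), len(x))
            assert approx == pytest.approx(exact, abs=0.10)


class TestSelectPredictors:
    def test_constructed_monotone_case_selects_plt(self):
        """Plt strictly increasing with survival, everything else near
        constant -> only PLT selected, with positive rho."""
        rng = np.random.default_rng(0)
        records = [
            make_record(
                patient_id=f"M{i}",
                survival_days=i + 1,
                neu=5.0 + 1e-3 * rng.standard_normal(),
                lym=1.5 + 1e-3 * rng.standard_normal(),
                rbc=4.0 + 1e-3 * rng.standard_normal(),
                hb=120.0 + 1e-3 * rng.standard_normal(),
                plt=100.0 + 5.0 * i,
            )
            for i in range(30)
        ]
        results = {r.parameter: r for r in select_predictors(records)}
        assert results[P.PLT].selected
        assert results[P.PLT].rho > 0.99

    def test_results_cover_all_parameters_in_order(self):
        records = [
            make_record(patient_id=f"A{i}", survival_days=i + 1, neu=float(i + 1))
            for i in range(6)
        ]
        results = select_predictors(records)
        assert [r.parameter for r in results] == list(P)

    def test_too_few_pairs_flagged_untestable(self):
        records = [
            make_record(patient_id=f"B{i}", survival_days=i + 1, neu=float(i))
            for i in range(3)
        ]
        for r in select_predictors(records):
            assert not r.testable
            assert not r.selected
            assert math.isnan(r.rho)

    def test_pairwise_deletion_counts_only_complete_pairs(self):
        records = [
            make_record(patient_id=f"C{i}", survival_days=i + 1, neu=float(i + 1))
            for i in range(8)
        ] + [make_record(patient_id="C9", survival_days=20)]
        results = {r.parameter: r for r in select_predictors(records)}
        assert results[P.NEU].n == 8
        assert results[P.PLT].n == 0 and not results[P.PLT].testable

    def test_constant_parameter_flagged_untestable_not_selected(self):
        records = [
            make_record(patient_id=f"D{i}", survival_days=i + 1, neu=7.7)
            for i in range(10)
        ]
        results = {r.parameter: r for r in select_predictors(records)}
        assert not results[P.NEU].testable

    def test_alpha_bounds_validated(self):
        with pytest.raises(ValueError):
            SelectionConfig(alpha=0.0)
        with pytest.raises(ValueError):
            SelectionConfig(alpha=1.0)
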