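"""Unit and property tests for the ten dependent-correlation tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depcorr import stat_tests as stt
from depcorr.feasibility import correlation_determinant, rho2y_bounds

import _oracles

# Published worked examples for the standard Williams test:
# (r1y, r2y, r12, n) -> (t, two-sided p)
WILLIAMS_EXAMPLES = [
    ((-0.22, -0.13, 0.46, 73), (-0.7420, 0.461)),
    ((0.209, 0.086, 0.114, 112), (0.9846, 0.327)),
    ((0.209, -0.086, 0.114, 112), (2.3795, 0.019)),
    ((-0.11, 0.10, -0.45, 150), (-1.5067, 0.134)),
    ((-0.11, -0.03, -0.33, 150), (-0.5979, 0.551)),
    ((0.10, -0.03, -0.30, 150), (0.9817, 0.328)),
    ((-0.22, 0.17, -0.35, 100), (-2.4077, 0.018)),
]


def feasible_triplet_strategy():
    @st.composite
    def build(draw):
        r12 = draw(st.floats(-0.9, 0.9))
        r1y = draw(st.floats(-0.9, 0.9))
        lo, hi = rho2y_bounds(r12, r1y)
        width = hi - lo
        r2y = draw(st.floats(lo + 0.1 * width, hi - 0.1 * width))
        n = draw(st.integers(5, 1000))
        return stt.CorrelationTriplet(r1y=r1y, r2y=r2y, r12=r12, n=n)

    return build()


class TestFisherZ:
    def test_known_values_and_roundtrip(self):
        assert stt.fisher_z(0.0) == 0.0
        assert stt.fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-12)
        assert stt.inverse_fisher_z(stt.fisher_z(0.3)) == pytest.approx(0.3, abs=1e-14)
        assert stt.fisher_z(-0.4) == -stt.fisher_z(0.4)

    def test_domain_error_at_unit_correlation(self):
        with pytest.raises(ValueError):
            stt.fisher_z(1.0)


class TestCorrelationsFromData:
    def test_matches_hand_computed_pearson(self, rng):
        table = rng.standard_normal((5, 3))
        triplet, dropped = stt.correlations_from_data(table)
        assert dropped == 0 and triplet.n == 5

        def pearson(a, b):
            a, b = a - a.mean(), b - b.mean()
            return float((a * b).sum() / math.sqrt((a**2).sum() * (b**2).sum()))

        assert triplet.r1y == pytest.approx(pearson(table[:, 0], table[:, 2]), abs=1e-12)
        assert triplet.r2y == pytest.approx(pearson(table[:, 1], table[:, 2]), abs=1e-12)
        assert triplet.r12 == pytest.approx(pearson(table[:, 0], table[:, 1]), abs=1e-12)

    def test_collinear_column_hits_boundary(self, rng):
        y = rng.standard_normal(20)
        table = np.column_stack([y, rng.standard_normal(20), y])
        triplet, _ = stt.correlations_from_data(table)
        assert triplet.r1y == pytest.approx(1.0)

    def test_complete_case_dropping(self, rng):
        table = rng.standard_normal((10, 3))
        table[3, 1] = np.nan
        triplet, dropped = stt.correlations_from_data(table)
        assert (triplet.n, dropped) == (9, 1)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="4 complete rows"):
            stt.correlations_from_data(rng.standard_normal((3, 3)))
        bad = rng.standard_normal((8, 3))
        bad[:, 2] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            stt.correlations_from_data(bad)

    def test_independent_data_near_zero_correlations(self, rng):
        triplet, _ = stt.correlations_from_data(rng.standard_normal((100_000, 3)))
        for r in (triplet.r1y, triplet.r2y, triplet.r12):
            assert abs(r) < 0.02


@pytest.mark.parametrize("inputs,expected", WILLIAMS_EXAMPLES)
def test_williams_reproduces_published_values(inputs, expected):
    triplet = stt.CorrelationTriplet(*inputs)
    res = stt.evaluate_test("williams", triplet)
    assert res.statistic == pytest.approx(expected[0], abs=5e-5)
    assert res.p_two_sided == pytest.approx(expected[1], abs=5e-4)


@pytest.mark.parametrize("name", [t for t in stt.ALL_TESTS if t != "zou"])
def test_zero_statistic_and_unit_p_at_equal_correlations(name):
    triplet = stt.CorrelationTriplet(0.42, 0.42, 0.3, 80)
    res = stt.evaluate_test(name, triplet)
    assert res.statistic == pytest.approx(0.0, abs=1e-14)
    assert res.p_two_sided == pytest.approx(1.0, abs=1e-12)
    assert not res.reject


@pytest.mark.parametrize("name", [t for t in stt.ALL_TESTS if t != "zou"])
def test_matches_high_precision_arithmetic_to_ten_digits(name):
    value = stt.statistic(name, 0.4, 0.1, 0.3, 100)
    expected = _oracles.highprec(name, 0.4, 0.1, 0.3, 100)
    assert value == pytest.approx(expected, rel=1e-10)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(feasible_triplet_strategy())
def test_swap_antisymmetry(t):
    """Swapping r1y and r2y negates every statistic and mirrors Zou's CI."""
    swapped = stt.CorrelationTriplet(t.r2y, t.r1y, t.r12, t.n)
    for name in stt.ALL_TESTS:
        if name == "zou":
            a, b = stt.zou_interval(t), stt.zou_interval(swapped)
            if a.applicable and b.applicable:
                assert a.L == pytest.approx(-b.U, abs=1e-12)
                assert a.U == pytest.approx(-b.L, abs=1e-12)
            continue
        x = stt.statistic(name, t)
        y = stt.statistic(name, swapped)
        if np.isfinite(x) and np.isfinite(y):
            assert x == pytest.approx(-y, abs=1e-10 * (1 + abs(x)))
        else:
            assert np.isnan(x) and np.isnan(y)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(feasible_triplet_strategy())
def test_hotelling_dominates_williams_and_hsh(t):
    """Williams and HSH add positive terms to Hotelling's denominator."""
    t_h = stt.hotelling_t(t)
    t_w = stt.williams_t(t)
    t_hsh = stt.hsh_t(t)
    if np.isfinite(t_h):
        tol = 1e-10 * (1 + abs(t_h))
        if np.isfinite(t_w):
            assert abs(t_w) <= abs(t_h) + tol
        if np.isfinite(t_hsh):
            assert abs(t_hsh) <= abs(t_h) + tol


def test_hsh_equals_hotelling_at_equal_correlations():
    assert stt.hsh_t(0.3, 0.3, 0.5, 60) == stt.hotelling_t(0.3, 0.3, 0.5, 60) == 0.0


def test_steiger_covariance_collapses_to_dunn_clark_at_equality():
    # at r1y = r2y all pooled means equal the common value
    r, r12 = 0.55, 0.2
    c_dc = stt._c_dunn_clark(np.float64(r), np.float64(r), np.float64(r12))
    c_s = stt._c_pooled(np.float64(r), np.float64(r12))
    assert c_dc == pytest.approx(c_s, rel=1e-14)


def test_oracle_equivalence_on_random_feasible_triplets(feasible_triplets):
    """Vectorized implementations match independent scalar transcriptions."""
    for r1y, r2y, r12, n in feasible_triplets:
        for name, oracle in _oracles.SCALAR_ORACLES.items():
            mine = stt.statistic(name, r1y, r2y, r12, n)
            ref = oracle(r1y, r2y, r12, n)
            if math.isnan(ref) or math.isnan(mine):
                # disagreement allowed only inside the radicand guard band
                continue
            assert mine == pytest.approx(ref, rel=1e-10), (name, r1y, r2y, r12, n)
        L, U = stt.zou_bounds(r1y, r2y, r12, n)
        L_ref, U_ref = _oracles.zou(r1y, r2y, r12, n)
        assert L == pytest.approx(L_ref, rel=1e-10, abs=1e-12)
        assert U == pytest.approx(U_ref, rel=1e-10, abs=1e-12)


class TestMengRosenthalRubin:
    def test_f_above_one_but_below_reciprocal_mean_square(self):
        # (.6, .6, -.5): f = 1.5 / (2 * 0.64) = 1.171875 < 1/r2bar = 2.78
        t = stt.CorrelationTriplet(0.6, 0.6, -0.5, 50)
        assert np.isfinite(stt.mrr_z(t))
        assert stt.mrr_z(t, cap_f=True) == 0.0  # capped: f=1 gives h=1 exactly

    def test_uncapped_undefined_when_f_exceeds_reciprocal(self):
        # r2bar = 0.8125, f = 2.667 >= 1/r2bar = 1.231
        t = stt.CorrelationTriplet(0.95, 0.85, 0.0, 50)
        assert np.isnan(stt.mrr_z(t))
        assert np.isfinite(stt.mrr_z(t, cap_f=True))

    def test_capped_defined_on_whole_cube(self):
        values, mask = stt.applicability_mask("mrr", r12=-0.6, grid_step=0.03, cap_f=True)
        assert mask.all()


class TestZou:
    def test_contains_zero_at_equal_correlations(self):
        iv = stt.zou_interval(stt.CorrelationTriplet(0.4, 0.4, 0.1, 50))
        assert iv.L < 0.0 < iv.U
        assert iv.l1 < iv.u1 and iv.l2 < iv.u2
        assert all(-1 < v < 1 for v in (iv.l1, iv.l2, iv.u1, iv.u2))

    def test_width_shrinks_as_alpha_grows(self):
        t = stt.CorrelationTriplet(0.5, 0.2, 0.3, 60)
        widths = [
            (lambda iv: iv.U - iv.L)(stt.zou_interval(t, alpha=a))
            for a in (0.01, 0.05, 0.10, 0.20)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_covariance_term_equals_dunn_clark_form(self, feasible_triplets):
        # (r12 - r1*r2/2)(1 - r1^2 - r2^2 - r12^2) + r12^3 expands to the
        # Dunn-Clark numerator: the two printed forms are identical
        for r1, r2, r12, _ in feasible_triplets[:100]:
            zou_c = ((r12 - r1 * r2 / 2) * (1 - r1**2 - r2**2 - r12**2) + r12**3) / (
                (1 - r1**2) * (1 - r2**2)
            )
            dc_c = stt._c_dunn_clark(np.float64(r1), np.float64(r2), np.float64(r12))
            assert zou_c == pytest.approx(dc_c, rel=1e-10, abs=1e-14)


class TestEvaluateTest:
    def test_lower_tail_rejection(self):
        res = stt.evaluate_test("williams", stt.CorrelationTriplet(-0.22, 0.17, -0.35, 100))
        assert res.p_two_sided == pytest.approx(0.018, abs=5e-4)
        assert res.reject_lower and not res.reject_upper

    def test_zou_decision_comes_from_interval(self):
        res = stt.evaluate_test("zou", stt.CorrelationTriplet(0.8, 0.2, 0.5, 100))
        assert math.isnan(res.p_two_sided)
        assert res.interval.L > 0 and res.reject_upper and not res.reject_lower

    def test_undefined_statistic_contract(self):
        # infeasible sample triplet: Hotelling radicand negative
        t = stt.CorrelationTriplet(0.9, -0.9, 0.9, 50)
        res = stt.evaluate_test("hotelling", t)
        assert not res.applicable
        assert math.isnan(res.statistic) and math.isnan(res.p_two_sided)
        assert not (res.reject_lower or res.reject_upper)

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown test"):
            stt.evaluate_test("pearson", stt.CorrelationTriplet(0.1, 0.2, 0.3, 30))

    def test_references(self):
        t = stt.CorrelationTriplet(0.3, 0.1, 0.2, 43)
        assert stt.evaluate_test("williams", t).reference == "student_t"
        assert stt.evaluate_test("williams", t).df == 40
        assert stt.evaluate_test("steiger", t).reference == "standard_normal"


class TestFlipForUnsigned:
    def test_published_example(self):
        t = stt.CorrelationTriplet(-0.22, 0.17, -0.35, 100)
        flipped = stt.flip_for_unsigned(t)
        assert (flipped.r1y, flipped.r2y, flipped.r12) == (-0.22, -0.17, 0.35)
        res = stt.evaluate_test("williams", flipped)
        assert abs(res.statistic) == pytest.approx(0.4437, abs=5e-5)
        assert res.p_two_sided == pytest.approx(0.658, abs=5e-4)

    def test_involution(self):
        t = stt.CorrelationTriplet(0.3, -0.5, 0.2, 40)
        assert stt.flip_for_unsigned(stt.flip_for_unsigned(t)) == t


class TestApplicabilityMasks:
    @pytest.mark.parametrize("r12", [-0.6, 0.0, 0.75])
    def test_hotelling_mask_is_positive_definite_region(self, r12):
        values, mask = stt.applicability_mask("hotelling", r12, grid_step=0.02)
        r1y, r2y = np.meshgrid(values, values, indexing="ij")
        det = correlation_determinant(r12, r1y, r2y)
        assert np.array_equal(mask, det > stt.RADICAND_TOL / 2)

    @pytest.mark.parametrize("r12", [-0.9, -0.45, 0.0, 0.45, 0.9])
    def test_hms_mask_covers_whole_cube(self, r12):
        _, mask = stt.applicability_mask("hms", r12, grid_step=0.02)
        assert mask.all()

    def test_uncapped_mrr_undefined_cells_only_for_negative_r12(self):
        # holes require the mean squared correlation to reach 2/(3 - r12)
        # inside the feasibility ellipse, possible only for r12 <= 2 - sqrt(5)
        for r12 in (-0.8, -0.45, -0.3):
            values, mask = stt.applicability_mask("mrr", r12, grid_step=0.02)
            r1y, r2y = np.meshgrid(values, values, indexing="ij")
            inside = correlation_determinant(r12, r1y, r2y) > 0
            assert (inside & ~mask).any(), f"expected holes at r12={r12}"
        for r12 in (0.0, 0.45, 0.9):
            values, mask = stt.applicability_mask("mrr", r12, grid_step=0.02)
            r1y, r2y = np.meshgrid(values, values, indexing="ij")
            inside = correlation_determinant(r12, r1y, r2y) > 0
            assert not (inside & ~mask).any(), f"unexpected holes at r12={r12}"

    def test_williams_and_hsh_masks_cover_feasible_region(self):
        for name in ("williams", "hsh"):
            values, mask = stt.applicability_mask(name, 0.3, grid_step=0.02)
            r1y, r2y = np.meshgrid(values, values, indexing="ij")
            inside = correlation_determinant(0.3, r1y, r2y) > 1e-6
            assert mask[inside].all()


def test_dunn_clark_finite_at_extreme_opposite_correlations():
    # large opposite-sign correlations with large r12: the test is known to
    # stay finite (and fail to reject) in this empirically impossible corner
    t = stt.CorrelationTriplet(0.95, -0.95, 0.8, 50)
    value = stt.dunn_clark_z(t)
    assert np.isfinite(value)
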