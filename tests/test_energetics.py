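"""Transition-state-theory conversions and free-energy profile classification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from kinetrap.energetics import (
    BinderClass,
    FreeEnergyProfile,
    ProfileState,
    ThermalContext,
    apply_uniform_shift,
    barrier_rate,
    classify_binder,
    ddg_from_fold,
    fold_from_ddg,
    halflife_from_rate,
    rate_from_halflife,
)

CTX = ThermalContext()  # R = 1.987e-3 kcal/mol/K, T = 298 K


def simple_profile(g_sub=0.0, g_barrier=5.0, g_prod=-2.0, branch="unbound"):
    return FreeEnergyProfile(
        branch=branch,
        states=(
            ProfileState.ground("S", g_sub),
            ProfileState.barrier("S_ts", g_barrier),
            ProfileState.ground("P", g_prod),
        ),
    )


class TestScalarConversions:
    def test_ten_fold_is_about_1p4_kcal(self):
        ddg = ddg_from_fold(10.0, CTX)
        assert ddg == pytest.approx(1.364, abs=2e-3)
        assert round(ddg, 1) == 1.4

    def test_hundred_fold_increment(self):
        # RT·ln(100) evaluated directly; two printed 1.4 increments give 2.8
        assert ddg_from_fold(100.0, CTX) == pytest.approx(2.727, abs=3e-3)
        assert 2 * round(ddg_from_fold(10.0, CTX), 1) == pytest.approx(2.8)

    def test_no_destabilization_no_rate_change(self):
        assert ddg_from_fold(1.0, CTX) == 0.0
        assert fold_from_ddg(0.0, CTX) == 1.0

    def test_rounded_1p4_overstates_the_fold(self):
        # the printed 1.4 kcal/mol corresponds to a 10.63-fold slowing
        assert fold_from_ddg(1.4, CTX) == pytest.approx(10.63, abs=0.05)

    def test_rt_ln10_anchor(self):
        assert 1.36 <= CTX.rt * math.log(10.0) <= 1.37

    @pytest.mark.parametrize("bad", [0.5, 0.0, -1.0])
    def test_fold_below_one_rejected(self, bad):
        with pytest.raises(ValueError):
            ddg_from_fold(bad, CTX)

    def test_negative_ddg_rejected(self):
        with pytest.raises(ValueError):
            fold_from_ddg(-0.1, CTX)

    @pytest.mark.parametrize(
        "t_half, expected",
        [(math.log(2.0), 1.0), (693.15, pytest.approx(1.0e-3, rel=1e-4))],
    )
    def test_rate_from_halflife(self, t_half, expected):
        assert rate_from_halflife(t_half) == expected

    def test_halflife_rate_inverse_pair(self):
        for k in (1e-5, 1e-3, 2.0):
            assert rate_from_halflife(halflife_from_rate(k)) == pytest.approx(
                k, rel=1e-12
            )

    def test_nonpositive_halflife_rejected(self):
        with pytest.raises(ValueError):
            rate_from_halflife(0.0)

    @settings(derandomize=True, max_examples=200)
    @given(fold=st.floats(min_value=1.0, max_value=1e6))
    def test_round_trip_identity(self, fold):
        assert fold_from_ddg(ddg_from_fold(fold, CTX), CTX) == pytest.approx(
            fold, rel=1e-12
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=1.0, max_value=1e6),
        b=st.floats(min_value=1.0, max_value=1e6),
    )
    def test_strict_monotonicity(self, a, b):
        if a < b:
            assert ddg_from_fold(a, CTX) < ddg_from_fold(b, CTX)
        elif a > b:
            assert ddg_from_fold(a, CTX) > ddg_from_fold(b, CTX)


class TestProfiles:
    def test_alternation_enforced(self):
        with pytest.raises(ValueError):
            FreeEnergyProfile(
                branch="u",
                states=(
                    ProfileState.ground("S", 0.0),
                    ProfileState.ground("P", -1.0),
                ),
            )

    def test_barrier_below_ground_rejected(self):
        with pytest.raises(ValueError):
            simple_profile(g_sub=0.0, g_barrier=-1.0)

    def test_barrier_rate_equals_prefactor_at_zero_height(self):
        prof = simple_profile(g_barrier=0.0, g_prod=-5.0)
        assert barrier_rate(prof, "S", "S_ts", prefactor=3.0).value == 3.0

    def test_equal_barriers_give_equal_rates(self):
        # uniform binding: both branches share the same activation energy
        unbound = simple_profile()
        bound = apply_uniform_shift(unbound, 3.0)
        k_u = barrier_rate(unbound, "S", "S_ts").value
        k_b = barrier_rate(bound, "S", "S_ts").value
        assert k_b == pytest.approx(k_u, rel=1e-12)

    def test_raised_bound_barrier_slows_ten_fold(self):
        unbound = simple_profile()
        ddg = ddg_from_fold(10.0, CTX)
        bound = simple_profile(g_barrier=5.0 + ddg, branch="bound")
        k_u = barrier_rate(unbound, "S", "S_ts").value
        k_b = barrier_rate(bound, "S", "S_ts").value
        assert k_b == pytest.approx(k_u / 10.0, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(min_value=-10, max_value=10))
    def test_uniform_shift_preserves_barrier_heights(self, shift):
        prof = simple_profile()
        shifted = apply_uniform_shift(prof, shift)
        assert shifted.barrier_heights() == pytest.approx(prof.barrier_heights())

    def test_zero_shift_is_identity(self):
        prof = simple_profile()
        assert apply_uniform_shift(prof, 0.0) == prof

    def test_roundtrip_yaml(self):
        prof = simple_profile()
        assert FreeEnergyProfile.from_yaml(prof.to_yaml()) == prof


def two_route_profile(branch, b1=5.0, b2=4.0, shift=0.0):
    """S with two barriers/products laid out as P1-route then P2-route."""
    return FreeEnergyProfile(
        branch=branch,
        states=(
            ProfileState.ground("P1", -2.0 - shift),
            ProfileState.barrier("S_ts1", b1 - shift),
            ProfileState.ground("S", 0.0 - shift),
            ProfileState.barrier("S_ts2", b2 - shift),
            ProfileState.ground("P2", -3.0 - shift),
        ),
    )


class TestClassification:
    def test_uniform_shift_classified_uniform(self):
        u = two_route_profile("unbound")
        b = two_route_profile("bound", shift=3.0)
        assert classify_binder(u, b) is BinderClass.UNIFORM

    def test_raised_p2_barrier_is_negative_catalysis(self):
        u = two_route_profile("unbound")
        b = two_route_profile("bound", b2=4.0 + 1.4, shift=3.0)
        # relative destabilization of the bound P2 transition state only
        assert classify_binder(u, b) is BinderClass.NEGATIVE_CATALYSIS

    def test_lowered_barrier_is_positive_catalysis(self):
        u = two_route_profile("unbound")
        b = two_route_profile("bound", b1=5.0 - 1.0, shift=3.0)
        assert classify_binder(u, b) is BinderClass.POSITIVE_CATALYSIS

    def test_both_directions_is_mixed(self):
        u = two_route_profile("unbound")
        b = two_route_profile("bound", b1=4.5, b2=4.5, shift=3.0)
        assert classify_binder(u, b) is BinderClass.MIXED

    def test_mismatched_states_rejected(self):
        u = two_route_profile("unbound")
        b = simple_profile(branch="bound")
        with pytest.raises(ValueError):
            classify_binder(u, b)
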