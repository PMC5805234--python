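"""Unit and property tests of the whole-body rate equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glucoloop as gl
from glucoloop.whole_body import WHOLE_BODY_STATE_NAMES

from reference_rhs import reference_whole_body_rhs


def test_heaviside_is_right_continuous():
    assert gl.heaviside_switch(0.0) == 1
    assert gl.heaviside_switch(-10.0) == 0
    assert gl.heaviside_switch(3.7) == 1
    with pytest.raises(ValueError):
        gl.heaviside_switch(float("nan"))
    with pytest.raises(ValueError):
        gl.heaviside_switch(float("inf"))


def test_smoothed_heaviside_approaches_step():
    u = gl.smoothed_heaviside(steepness=100.0)
    assert u(0.0) == pytest.approx(0.5)
    assert u(1.0) == pytest.approx(1.0, abs=1e-10)
    assert u(-1.0) == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError):
        gl.smoothed_heaviside(-1.0)


class TestGlucagonRate:
    def test_fixed_point_above_threshold(self, ngr_preset):
        """Above Ge the secretion gate is off and E = c0/c3 is stationary."""
        p = ngr_preset.whole_body
        E_star = p.c0 / p.c3
        assert gl.glucagon_rate(p.Ge + 20.0, 10.0, E_star, p) == pytest.approx(0.0)

    def test_only_basal_term(self, ngr_preset):
        p = ngr_preset.whole_body.replace(c0=1.0, c3=0.5)
        assert gl.glucagon_rate(p.Ge + 1.0, 1.0, 0.0, p) == pytest.approx(1.0)

    def test_hand_evaluated_gated_secretion(self, ngr_preset):
        # c0 + c1/(c2 + I e) (Ge - G) u - c3 E with the adopted grouping
        p = ngr_preset.whole_body.replace(
            c0=1.0, c1=2.0, c2=1.0, e=1.0, Ge=100.0, c3=0.1)
        assert gl.glucagon_rate(90.0, 1.0, 10.0, p) == pytest.approx(10.0)

    def test_zero_denominator_raises(self, ngr_preset):
        p = ngr_preset.whole_body.replace(c2=0.0)
        with pytest.raises(ZeroDivisionError):
            gl.glucagon_rate(50.0, 0.0, 10.0, p)


class TestHungerRate:
    def test_single_surviving_term(self, ngr_preset):
        p = ngr_preset.whole_body.replace(b17=1.0)
        assert gl.hunger_rate(Q=1.0, Y=0.0, I=0.0, G=50.0, H=0.0,
                              p=p) == pytest.approx(1.0)

    def test_nonnegative_at_zero_hunger(self, ngr_preset):
        p = ngr_preset.whole_body
        assert gl.hunger_rate(Q=500.0, Y=8.0, I=30.0, G=150.0, H=0.0, p=p) >= 0

    def test_leptin_halves_drive(self, ngr_preset):
        """b18*Y = 1 halves the appetite drive relative to Y = 0."""
        p = ngr_preset.whole_body
        y_half = 1.0 / p.b18
        full = gl.hunger_rate(Q=100.0, Y=0.0, I=0.0, G=0.0, H=0.0, p=p)
        halved = gl.hunger_rate(Q=100.0, Y=y_half, I=0.0, G=0.0, H=0.0, p=p)
        assert halved == pytest.approx(full / 2.0)


class TestInterstitialRates:
    def test_drive_vanishes_at_basal(self, ngr_preset):
        p = ngr_preset.whole_body
        d_ins, _ = gl.interstitial_rates(p.Ib, p.Gb, 3.0, 0.0, p)
        assert d_ins == pytest.approx(-p.p2U * 3.0)

    def test_floored_below_basal(self, ngr_preset):
        """A plasma dip below basal cannot pull the deviations negative."""
        p = ngr_preset.whole_body
        d_ins, d_gt = gl.interstitial_rates(p.Ib - 5.0, p.Gb - 10.0, 0.0, 0.0, p)
        assert d_ins == 0.0 and d_gt == 0.0

    def test_single_term_glucose_drive(self, ngr_preset):
        p = ngr_preset.whole_body.replace(q2=2.0)
        _, d_gt = gl.interstitial_rates(p.Ib, p.Gb + 1.0, 0.0, 0.0, p)
        assert d_gt == pytest.approx(2.0)


class TestWholeBodyRhs:
    def test_empty_system_fixed_point(self, ngr_preset):
        p = ngr_preset.whole_body.replace(s=0.0, b23=0.0, c0=0.0,
                                          b12=0.0, Ge=0.0)
        d = gl.whole_body_rhs(np.zeros(14), 0.0, p)
        np.testing.assert_array_equal(d, np.zeros(14))

    def test_single_pathway_activation(self, ngr_preset):
        """One mg of intestinal glucose feeds plasma and incretins only."""
        p = ngr_preset.whole_body.replace(
            b10=1.0, f=1.0, v=1.0, s=0.0, b23=0.0, c0=0.0,
            b12=0.0, Ge=0.0)
        state = np.zeros(14)
        state[WHOLE_BODY_STATE_NAMES.index("L")] = 1.0
        d = dict(zip(WHOLE_BODY_STATE_NAMES, gl.whole_body_rhs(state, 0.0, p)))
        assert d["G"] == pytest.approx(1.0)
        assert d["L"] == pytest.approx(-1.0)
        assert d["W"] == pytest.approx(p.b6)

    def test_negative_state_rejected(self, ngr_preset):
        state = np.zeros(14)
        state[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            gl.whole_body_rhs(state, 0.0, ngr_preset.whole_body)
        with pytest.raises(ValueError, match="uptake_flux"):
            gl.whole_body_rhs(np.zeros(14), -1.0, ngr_preset.whole_body)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_transcription(self, seed):
        """Randomized states agree with a hand-coded second transcription
        of the equations to 1e-12 relative."""
        preset = gl.condition_preset("NGR")
        rng = np.random.default_rng(seed)
        state = rng.uniform(0.0, 1.0, 14) * np.array(
            [3e4, 3e4, 200.0, 60.0, 100.0, 150.0, 5e3, 5e3, 5e3, 30.0,
             1500.0, 5e4, 50.0, 80.0])
        uptake = float(rng.uniform(0.0, 20.0))
        got = gl.whole_body_rhs(state, uptake, preset.whole_body)
        want = reference_whole_body_rhs(
            dict(zip(WHOLE_BODY_STATE_NAMES, state)), uptake,
            preset.whole_body)
        for name, g in zip(WHOLE_BODY_STATE_NAMES, got):
            assert g == pytest.approx(want[name], rel=1e-12, abs=1e-300), name


def test_mass_bookkeeping_stomach_to_intestine(ngr_preset, rng):
    """The stomach-to-intestine flux b8*S appears with opposite signs and
    the intestine-to-plasma transfer is scaled by f/v."""
    p = ngr_preset.whole_body
    state = rng.uniform(0.1, 1.0, 14) * 100.0
    d = dict(zip(WHOLE_BODY_STATE_NAMES, gl.whole_body_rhs(state, 0.0, p)))
    S, L, H = (state[WHOLE_BODY_STATE_NAMES.index(n)] for n in "SLH")
    assert d["S"] + d["L"] == pytest.approx(p.b9 * H - p.b10 * L, rel=1e-12)
    d2 = dict(zip(WHOLE_BODY_STATE_NAMES,
                  gl.whole_body_rhs(state, 0.0, p.replace(b8=2 * p.b8))))
    assert d2["S"] - d["S"] == pytest.approx(-(d2["L"] - d["L"]), rel=1e-12)


@pytest.mark.parametrize("var,partial,sign", [
    ("S", "Q", -1.0),   # ghrelin secretion decreasing in stomach glucose
    ("I", "Q", -1.0),   # ghrelin secretion decreasing in insulin
    ("Y", "H", -1.0),   # appetite drive decreasing in leptin
    ("Q", "H", +1.0),   # appetite drive increasing in ghrelin
    ("I", "H", -1.0),   # appetite drive decreasing in insulin
])
def test_hormonal_coupling_signs(ngr_preset, var, partial, sign):
    """Finite-difference sign checks of the ghrelin and hunger couplings."""
    p = ngr_preset.whole_body
    base = np.array([5e3, 5e3, 100.0, 20.0, 30.0, 70.0, 4e3, 2e3, 3e3,
                     10.0, 500.0, 0.0, 5.0, 10.0])
    i = WHOLE_BODY_STATE_NAMES.index(var)
    j = WHOLE_BODY_STATE_NAMES.index(partial)
    bumped = base.copy()
    bumped[i] += 1e-4 * max(base[i], 1.0)
    d0 = gl.whole_body_rhs(base, 0.0, p)[j]
    d1 = gl.whole_body_rhs(bumped, 0.0, p)[j]
    assert sign * (d1 - d0) > 0


def test_flow_preserves_nonnegative_orthant(ngr_preset, rng):
    """Every structurally guarded component has derivative >= 0 whenever it
    sits at 0 (liver mass C is the exception: its production balance can be
    transiently negative and is kept positive by calibration instead)."""
    p = ngr_preset.whole_body
    guarded = [n for n in WHOLE_BODY_STATE_NAMES if n != "C"]
    for _ in range(50):
        state = rng.uniform(0.0, 1.0, 14) * np.array(
            [3e4, 3e4, 200.0, 60.0, 100.0, 150.0, 5e3, 5e3, 5e3, 30.0,
             1500.0, 5e4, 50.0, 80.0])
        for name in guarded:
            z = state.copy()
            z[WHOLE_BODY_STATE_NAMES.index(name)] = 0.0
            d = gl.whole_body_rhs(z, float(rng.uniform(0, 10)), p)
            assert d[WHOLE_BODY_STATE_NAMES.index(name)] >= 0.0, name


def test_clamped_glucagon_relaxes_to_ratio(ngr_preset):
    """With G held above Ge and I constant, E converges exponentially to
    c0/c3 at rate c3."""
    p = ngr_preset.whole_body
    cfg = gl.SimulationConfig(duration=10.0 / p.c3, output_dt=1.0)
    traj = gl.simulate_clamped(ngr_preset, cfg,
                               {"G": p.Ge + 30.0, "I": p.Ib})
    E = traj["E"]
    E_star = p.c0 / p.c3
    assert E[-1] == pytest.approx(E_star, rel=1e-3)
    # exponential rate check at half horizon
    t = traj.time
    mid = len(t) // 2
    expected = E_star + (E[0] - E_star) * math.exp(-p.c3 * t[mid])
    assert E[mid] == pytest.approx(expected, rel=1e-3)


def test_params_validation_rejects_bad_domains(ngr_preset):
    p = ngr_preset.whole_body
    with pytest.raises(ValueError, match="f"):
        p.replace(f=1.5).validate()
    with pytest.raises(ValueError, match="e"):
        p.replace(e=0.0).validate()
    with pytest.raises(ValueError, match="b2"):
        p.replace(b2=-0.1).validate()
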