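"""Tests of steady-state parameter derivation, estimation and range checks."""

import numpy as np
import pytest

import glucoloop as gl
from glucoloop.parameter_workflow import (
    EstimationReport,
    PhysiologicalRanges,
    constrained_estimate,
    derive_steady_state_params,
    steady_state_residuals,
    validate_ranges,
)


class TestSteadyStateDerivation:
    def test_glucagon_elimination_ratio(self, ngr_preset):
        """Above the glucose threshold, c3 = c0/E0."""
        p = ngr_preset.whole_body.replace(c0=1.0)
        x0 = ngr_preset.initial_whole_body.replace(E=10.0, G=p.Ge + 5.0)
        derived = derive_steady_state_params(x0, p)
        assert derived["c3"] == pytest.approx(0.1)

    def test_leptin_secretion_rate(self, ngr_preset):
        """b13 = b14*Y0*Fat/A0 from the leptin balance."""
        p = ngr_preset.whole_body.replace(b14=0.1, Fat=20.0)
        x0 = ngr_preset.initial_whole_body.replace(Y=5.0, A=100.0)
        derived = derive_steady_state_params(x0, p)
        assert derived["b13"] == pytest.approx(0.1 * 5.0 * 20.0 / 100.0)

    @pytest.mark.parametrize("tag", ["NGR", "T2DM"])
    def test_substitute_back_residuals(self, tag, ngr_preset, t2dm_preset):
        """Every targeted equation is stationary at t=0 to 1e-10."""
        preset = {"NGR": ngr_preset, "T2DM": t2dm_preset}[tag]
        residuals = steady_state_residuals(preset.initial_whole_body,
                                           preset.whole_body)
        assert max(residuals.values()) < 1e-10

    def test_insulin_split_by_incretin_fraction(self, ngr_preset):
        p = ngr_preset.whole_body
        x0 = ngr_preset.initial_whole_body
        for rho in (0.2, 0.5, 0.8):
            d = derive_steady_state_params(x0, p, rho=rho)
            assert d["c"] * x0.W * x0.G == pytest.approx(rho * p.b2 * x0.I)
            assert d["b4"] * x0.G == pytest.approx((1 - rho) * p.b2 * x0.I)

    def test_b13_monotone_dependence(self, ngr_preset):
        """b13 rises linearly in Y0 and Fat, falls in A0."""
        p = ngr_preset.whole_body
        x0 = ngr_preset.initial_whole_body
        b13 = derive_steady_state_params(x0, p)["b13"]
        doubled_y = derive_steady_state_params(x0.replace(Y=2 * x0.Y), p)["b13"]
        assert doubled_y == pytest.approx(2 * b13)
        doubled_fat = derive_steady_state_params(
            x0, p.replace(Fat=2 * p.Fat))["b13"]
        assert doubled_fat == pytest.approx(2 * b13)
        doubled_a = derive_steady_state_params(x0.replace(A=2 * x0.A), p)["b13"]
        assert doubled_a == pytest.approx(b13 / 2)

    def test_zero_denominator_names_offender(self, ngr_preset):
        p = ngr_preset.whole_body
        with pytest.raises(ZeroDivisionError, match="M0"):
            derive_steady_state_params(
                ngr_preset.initial_whole_body.replace(M=0.0), p)

    def test_invalid_rho_rejected(self, ngr_preset):
        with pytest.raises(ValueError, match="rho"):
            derive_steady_state_params(ngr_preset.initial_whole_body,
                                       ngr_preset.whole_body, rho=1.5)


class TestValidateRanges:
    def make_traj(self, values):
        t = np.arange(float(len(values)))
        return gl.Trajectory(t, {"G": np.asarray(values, dtype=float)})

    def test_midband_trace_passes(self):
        ranges = PhysiologicalRanges({"G": (60.0, 200.0)})
        traj = self.make_traj([130.0] * 20)
        assert validate_ranges(traj, ranges) == []

    def test_touching_bound_is_compliant(self):
        """The bands are closed intervals: touching HL is not a violation."""
        ranges = PhysiologicalRanges({"G": (60.0, 200.0)})
        traj = self.make_traj([130.0, 200.0, 130.0, 60.0])
        assert validate_ranges(traj, ranges) == []

    def test_single_excursion_reported(self):
        ranges = PhysiologicalRanges({"G": (60.0, 200.0)})
        traj = self.make_traj([130.0, 210.0, 205.0, 130.0])
        violations = validate_ranges(traj, ranges)
        assert len(violations) == 2
        assert all(v.side == "above" and v.bound == 200.0 for v in violations)

    def test_transient_window_ignored(self):
        ranges = PhysiologicalRanges({"G": (60.0, 200.0)})
        traj = self.make_traj([300.0, 300.0, 130.0, 130.0])
        assert validate_ranges(traj, ranges, transient=2.0) == []

    def test_missing_entry_raises(self):
        ranges = PhysiologicalRanges({"I": (2.0, 80.0)})
        with pytest.raises(KeyError, match="'G'"):
            validate_ranges(self.make_traj([100.0]), ranges)

    def test_unbounded_marker_skips_variable(self):
        ranges = PhysiologicalRanges({"G": None})
        assert validate_ranges(self.make_traj([1e9]), ranges) == []

    def test_violation_fixture_windows(self):
        """A synthetic trace with two excursion windows above HL yields
        violations in exactly those two intervals."""
        spec = gl.FixtureSpec(kind="range_violation", duration=300.0,
                              column="G", baseline=100.0,
                              violation_windows=((50.0, 60.0, 250.0),
                                                 (200.0, 220.0, 260.0)))
        traj = gl.generate_fixture(spec)
        ranges = PhysiologicalRanges({"G": (60.0, 200.0)})
        violations = validate_ranges(traj, ranges)
        times = np.array([v.time for v in violations])
        in_first = (times >= 50.0) & (times <= 60.0)
        in_second = (times >= 200.0) & (times <= 220.0)
        assert np.all(in_first | in_second)
        assert in_first.any() and in_second.any()


class TestConstrainedEstimate:
    def test_feasible_start_returns_unchanged(self, ngr_preset):
        """A starting point already satisfying every band is returned with
        no search iterations beyond its evaluation."""
        ranges = gl.load_ranges()
        cfg = gl.SimulationConfig(duration=200.0)
        report = constrained_estimate(ngr_preset, cfg, ["b9", "r"], ranges,
                                      seed=3)
        assert report.feasible
        assert report.n_evaluations == 1
        assert report.values["b9"] == pytest.approx(ngr_preset.whole_body.b9)
        assert report.values["r"] == pytest.approx(ngr_preset.whole_body.r)

    def test_one_parameter_search_reaches_feasible_interval(self, ngr_preset):
        """Starting from an infeasible interstitial transfer rate, the
        search returns a value restoring band compliance."""
        bad = ngr_preset
        import dataclasses
        bad = dataclasses.replace(
            bad, whole_body=bad.whole_body.replace(q2=2.0))
        ranges = gl.load_ranges()
        cfg = gl.SimulationConfig(duration=150.0)
        report = constrained_estimate(bad, cfg, ["q2"], ranges, seed=11,
                                      budget=40)
        assert report.feasible
        assert report.values["q2"] < 2.0

    def test_same_seed_reproduces_report(self, ngr_preset):
        import dataclasses
        bad = dataclasses.replace(
            ngr_preset, whole_body=ngr_preset.whole_body.replace(q2=2.0))
        ranges = gl.load_ranges()
        cfg = gl.SimulationConfig(duration=120.0)
        a = constrained_estimate(bad, cfg, ["q2"], ranges, seed=5, budget=25)
        b = constrained_estimate(bad, cfg, ["q2"], ranges, seed=5, budget=25)
        assert a.values == b.values
        assert a.objective_trace == b.objective_trace

    def test_unknown_parameter_rejected(self, ngr_preset, default_config):
        with pytest.raises(KeyError, match="b99"):
            constrained_estimate(ngr_preset, default_config, ["b99"],
                                 PhysiologicalRanges({}))


def test_report_serialization_roundtrip(tmp_path):
    report = EstimationReport(values={"b9": 0.02}, residuals={"hunger": 0.0},
                              seed=7)
    path = tmp_path / "report.json"
    gl.write_report(report, path)
    import json
    loaded = json.loads(path.read_text())
    assert loaded["values"]["b9"] == 0.02
    assert loaded["seed"] == 7
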