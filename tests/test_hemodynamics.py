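import numpy as np
import pytest

from burnsim.hemodynamics import (
    BurnSimulator,
    HemodynamicState,
    ModelConstants,
    PatientConfig,
    advance,
    baroreflex,
    cop_from_albumin,
    endothelium_from_damage,
    pain_pathway,
    renal_output,
    transcapillary_flux,
)
from burnsim.inflammation import init_from_burn

PATIENT = PatientConfig()
K = ModelConstants()


class TestCOP:
    def test_zero_albumin_gives_zero_cop(self):
        assert cop_from_albumin(0.0) == 0.0

    def test_baseline_calibration_identity(self):
        assert cop_from_albumin(PATIENT.albumin_g_l) == pytest.approx(
            PATIENT.cop_mmhg
        )

    def test_convexity_doubling_more_than_doubles(self):
        for c in (10.0, 20.0, 42.0):
            assert cop_from_albumin(2 * c) > 2 * cop_from_albumin(c)

    def test_monotone(self):
        grid = np.linspace(0, 80, 50)
        vals = [cop_from_albumin(c) for c in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            cop_from_albumin(-1.0)


class TestEndothelium:
    def test_intact_tissue_is_baseline(self):
        e = endothelium_from_damage(1.0)
        assert e.R_leak == pytest.approx(K.r_leak_baseline)

    def test_resistance_monotone_decreasing_in_damage(self):
        assert endothelium_from_damage(0.5).R_leak < endothelium_from_damage(0.9).R_leak

    def test_permeability_monotone_increasing_in_damage(self):
        assert (
            endothelium_from_damage(0.5).P_albumin
            > endothelium_from_damage(0.9).P_albumin
        )

    def test_maps_continuous_and_bounded(self):
        grid = np.linspace(0.0, 1.0, 101)
        rs = np.array([endothelium_from_damage(d).R_leak for d in grid])
        ps = np.array([endothelium_from_damage(d).P_albumin for d in grid])
        assert (rs > 0).all() and (ps > 0).all()
        # no jumps: neighbouring values stay within a few percent of range
        assert np.max(np.abs(np.diff(rs))) < 0.1 * (rs.max() - rs.min())
        assert np.max(np.abs(np.diff(ps))) < 0.1 * (ps.max() - ps.min())

    def test_invalid_damage_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            endothelium_from_damage(1.2)


def _baseline_snapshot(sim):
    return sim.snapshot(sim.initial_vector(0.0))


class TestStarlingFlux:
    def test_healthy_steady_state_filtration_equals_lymph(self, simulator):
        state = _baseline_snapshot(simulator)
        j_fluid, j_alb = transcapillary_flux(state, endothelium_from_damage(1.0))
        assert j_fluid == pytest.approx(simulator.L0, rel=1e-6)
        assert j_alb == pytest.approx(simulator.L0 * simulator.c_i0, rel=1e-6)

    def test_oncotic_dominance_gives_reabsorption(self, simulator):
        state = _baseline_snapshot(simulator)
        # strip albumin from the interstitium: plasma COP pulls fluid back
        dry = HemodynamicState(
            **{
                **state.__dict__,
                "A_interstitial": 0.0,
                "COP_interstitial": 0.0,
                "MAP": 40.0,
            }
        )
        j_fluid, _ = transcapillary_flux(dry, endothelium_from_damage(1.0))
        assert j_fluid < 0

    def test_flux_linear_in_resistance(self, simulator):
        state = _baseline_snapshot(simulator)
        e1 = endothelium_from_damage(1.0)
        e2 = type(e1)(R_leak=e1.R_leak / 2.0, P_albumin=e1.P_albumin)
        j1, _ = transcapillary_flux(state, e1)
        j2, _ = transcapillary_flux(state, e2)
        assert j2 == pytest.approx(2.0 * j1, rel=1e-9)

    def test_non_finite_inputs_raise(self, simulator):
        state = _baseline_snapshot(simulator)
        bad = HemodynamicState(**{**state.__dict__, "MAP": float("nan")})
        with pytest.raises(ValueError, match="non-finite"):
            transcapillary_flux(bad, endothelium_from_damage(1.0))


class TestBaroreflex:
    def test_at_setpoint_neutral(self):
        assert baroreflex(90.0, 90.0) == (1.0, 1.0)

    def test_hypotension_raises_both(self):
        hr, svr = baroreflex(72.0, 90.0)
        assert hr > 1.0 and svr > 1.0

    def test_hypertension_lowers_both(self):
        hr, svr = baroreflex(110.0, 90.0)
        assert hr < 1.0 and svr < 1.0

    def test_saturation_beyond_shoulder(self):
        """Response gain is largest near the setpoint and collapses far away."""
        gain_near = baroreflex(0.9 * 90, 90.0)[0] - baroreflex(1.0 * 90, 90.0)[0]
        gain_far = baroreflex(0.4 * 90, 90.0)[0] - baroreflex(0.5 * 90, 90.0)[0]
        assert gain_far < gain_near

    def test_nonpositive_map_raises(self):
        with pytest.raises(ValueError, match="positive"):
            baroreflex(0.0, 90.0)


class TestRenal:
    def test_baseline_identity(self):
        assert renal_output(PATIENT.map_mmhg, PATIENT.plasma_volume_l) == (
            pytest.approx(PATIENT.uo_ml_h)
        )

    def test_hypotension_reduces_uo(self):
        assert renal_output(0.8 * 90, 3.0) < PATIENT.uo_ml_h

    def test_monotone_grid(self):
        maps = np.linspace(50, 90, 9)
        vols = np.linspace(1.0, 3.0, 9)
        grid = np.array([[renal_output(m, v) for m in maps] for v in vols])
        assert (np.diff(grid, axis=0) >= 0).all()  # volume direction
        assert (np.diff(grid, axis=1) >= 0).all()  # pressure direction

    def test_anuric_below_pressure_floor(self):
        assert renal_output(45.0, 3.0) == 0.0


class TestPainPathway:
    def test_no_burn_is_neutral(self):
        pain, epi_mult, rr_mult = pain_pathway(0.0, 0.0)
        assert pain == 0.0 and epi_mult == 1.0 and rr_mult == 1.0

    def test_burn_raises_respiration(self):
        pain, _, rr_mult = pain_pathway(0.25, 0.0)
        assert pain > 0 and rr_mult > 1.0

    def test_analgesia_brings_respiration_toward_neutral(self):
        _, _, rr_untreated = pain_pathway(0.25, 0.0)
        _, _, rr_treated = pain_pathway(0.25, 1.0)
        assert 1.0 < rr_treated < rr_untreated


class TestCoupledRuns:
    def test_homeostasis_48h(self, untreated_runs):
        df = untreated_runs[0]
        assert np.max(np.abs(df.MAP - PATIENT.map_mmhg)) < 0.01 * PATIENT.map_mmhg
        assert np.max(np.abs(df.V_plasma - 3.0)) < 0.01 * 3.0
        assert np.max(np.abs(df.HR - 72.0)) < 0.01 * 72.0

    def test_fluid_conservation_every_step(self, untreated_runs, simulator):
        """d(V_plasma + V_interstitial + V_urine)/dt == intake, cumulatively."""
        for tbsa in (0, 25, 40):
            df = untreated_runs[tbsa]
            total = df.V_plasma + df.V_interstitial + df.V_urine_cum
            intake = simulator.maintenance_l_h * df.time_h + df.V_infused_cum
            drift = (total - intake) - total.iloc[0]
            assert np.max(np.abs(drift)) < 1e-4

    def test_albumin_conservation(self, untreated_runs):
        for tbsa in (0, 10, 25, 40):
            df = untreated_runs[tbsa]
            total = df.A_plasma + df.A_interstitial
            assert np.max(np.abs(total - total.iloc[0])) < 1e-3 * total.iloc[0]

    def test_severity_ordering_across_burn_sizes(self, untreated_runs):
        nadir_map = [untreated_runs[t].MAP.min() for t in (10, 25, 40)]
        nadir_vb = [untreated_runs[t].V_blood.min() for t in (10, 25, 40)]
        nadir_d = [untreated_runs[t].D.min() for t in (10, 25, 40)]
        for seq in (nadir_map, nadir_vb, nadir_d):
            assert seq[0] > seq[1] > seq[2]

    def test_small_burn_compensated(self, untreated_runs):
        df = untreated_runs[10]
        assert df.MAP.min() > 0.9 * PATIENT.map_mmhg

    def test_advance_holds_baseline(self, simulator):
        state = _baseline_snapshot(simulator)
        nxt = advance(state, init_from_burn(0.0), dt=1.0)
        assert nxt.MAP == pytest.approx(state.MAP, rel=1e-3)
        assert nxt.V_plasma == pytest.approx(state.V_plasma, rel=1e-3)

    def test_advance_with_damage_loses_plasma(self, simulator):
        state = _baseline_snapshot(simulator)
        burned = init_from_burn(0.40)
        damaged = type(burned)(TR=0.4, N=1.0, TNF=1.0, NO=1.0, D=0.5)
        nxt = advance(state, damaged, dt=1.0)
        assert nxt.V_plasma < state.V_plasma
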