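"""Lumped whole-body fluid and cardiovascular model for burn shock.

Two fluid compartments (vascular plasma, interstitium) exchange volume and
albumin across a capillary barrier whose hydraulic resistance and solute
permeability are controlled by the tissue-integrity variable D of the
inflammation model.  Starling forces drive the exchange:

    J_fluid = (P_cap - P_int - sigma * (COP_p - COP_i)) / R_leak

with colloid osmotic pressures (COP) computed from albumin concentration by a
convex Landis-Pappenheimer-like law.  A lymphatic return proportional to
interstitial over-filling closes the loop; at the healthy baseline filtration
and lymph balance exactly (the closure constants are derived, not tuned).

The cardiovascular side is a minimal closure: cardiac output is heart rate
times a stroke volume proportional to stressed vascular volume, and
MAP = CO x SVR in relative units.  A sigmoidal baroreflex drives HR and SVR
multipliers toward pressure-restoring targets with a short time constant and
saturates for large pressure deficits (the reflex can be overwhelmed).  Renal
urine output falls with pressure and plasma volume; the burn pain signal
raises epinephrine and respiration, and ketamine blunts pain while exerting a
direct transient pressor effect.

Units: volumes L, pressures mmHg, albumin g and g/L, time h, rates per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import inflammation as infl

__all__ = [
    "PatientConfig",
    "ModelConstants",
    "EndothelialState",
    "HemodynamicState",
    "BurnSimulator",
    "cop_from_albumin",
    "endothelium_from_damage",
    "transcapillary_flux",
    "baroreflex",
    "renal_output",
    "pain_pathway",
    "advance",
]


@dataclass(frozen=True)
class PatientConfig:
    """Baseline anthropometrics and vitals of the simulated patient.

    Defaults describe a 70 kg adult chosen so that the Parkland reference
    volume for a 25% burn (7 L / 24 h) is commensurate with the resuscitation
    volumes the protocol controller delivers.
    """

    body_mass_kg: float = 70.0
    blood_volume_l: float = 5.0
    plasma_volume_l: float = 3.0
    map_mmhg: float = 90.0
    hr_per_min: float = 72.0
    rr_per_min: float = 12.0
    uo_ml_h: float = 60.0
    albumin_g_l: float = 42.0
    cop_mmhg: float = 25.0

    def __post_init__(self) -> None:
        vals = [
            self.body_mass_kg,
            self.blood_volume_l,
            self.plasma_volume_l,
            self.map_mmhg,
            self.hr_per_min,
            self.rr_per_min,
            self.uo_ml_h,
            self.albumin_g_l,
            self.cop_mmhg,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all patient baseline values must be positive")
        if self.plasma_volume_l >= self.blood_volume_l:
            raise ValueError("plasma volume must be smaller than blood volume")

    @property
    def rbc_volume_l(self) -> float:
        return self.blood_volume_l - self.plasma_volume_l


@dataclass(frozen=True)
class ModelConstants:
    """Closure constants of the fluid/cardiovascular model (units noted)."""

    sigma: float = 0.90               # albumin reflection coefficient
    r_leak_baseline: float = 40.0     # mmHg h / L
    p_cap_baseline: float = 20.0      # mmHg, capillary hydrostatic at rest
    p_cap_floor: float = 6.0          # mmHg, capillary pressure as MAP -> 0
    p_int_baseline: float = 0.0       # mmHg, interstitial hydrostatic at rest
    interstitial_compliance: float = 0.4   # mmHg per L of over-filling
    interstitial_volume_l: float = 10.5
    cop_interstitial_baseline: float = 8.0  # mmHg
    cop_linear: float = 0.21          # mmHg per g/L (linear COP coefficient)
    lymph_exponent: float = 2.0
    # leak / permeability response to damage (1 - D)
    r_leak_floor: float = 0.03        # fraction of baseline R at D = 0
    r_leak_power: float = 5.0
    perm_amplification: float = 120.0  # fold increase of PS at D = 0
    perm_power: float = 1.5
    # cardiovascular closure
    unstressed_blood_l: float = 3.0
    sv_smoothing: float = 0.05
    exchange_collapse_l: float = 0.3  # plasma volume of capillary derecruitment
    co_baseline_l_min: float = 5.0
    baro_gain_hr: float = 0.9
    baro_gain_svr: float = 0.7
    baro_width: float = 0.25          # fractional MAP error at reflex shoulder
    baro_tau_h: float = 0.05
    no_vasodilation: float = 0.15     # SVR reduction per unit NO
    # renal
    renal_anuria_map: float = 50.0    # mmHg, no filtration below this
    renal_pressure_exp: float = 1.5
    renal_volume_exp: float = 1.0
    renal_epi_suppression: float = 0.5  # sympathetic renal vasoconstriction
    renal_damage_suppression: float = 6.0  # filtration downregulation with injury
    # pain / epinephrine / respiration
    pain_tbsa_gain: float = 3.0       # pain 10/10 at TBSA >= 1/gain
    pain_analgesia_gain: float = 2.0
    epi_pain_gain: float = 1.0        # epinephrine units at pain 10/10
    epi_hr_gain: float = 0.25
    epi_svr_gain: float = 0.10
    rr_pain_gain: float = 0.6
    # ketamine
    ketamine_ref_dose_mg: float = 20.0
    ketamine_elimination: float = 1.0  # 1/h
    ketamine_pressor: float = 0.05     # direct SVR gain per unit effect
    ketamine_epi: float = 1.0          # sympathomimetic epinephrine per unit effect
    # maintenance fluid intake balancing baseline urine output
    maintenance_on: bool = True
    evaporative_loss_on: bool = False
    evaporative_l_h_per_tbsa: float = 0.06  # L/h per unit TBSA fraction, if enabled


@dataclass(frozen=True)
class EndothelialState:
    """Barrier state: hydraulic resistance and albumin permeability-surface."""

    R_leak: float      # mmHg h / L
    P_albumin: float   # L/h (permeability-surface clearance)

    def __post_init__(self) -> None:
        if self.R_leak <= 0 or self.P_albumin < 0:
            raise ValueError("invalid endothelial state")


@dataclass(frozen=True)
class HemodynamicState:
    """Snapshot of the fluid and cardiovascular state at one instant."""

    V_plasma: float
    V_interstitial: float
    V_urine_cum: float
    A_plasma: float
    A_interstitial: float
    COP_plasma: float
    COP_interstitial: float
    MAP: float
    HR: float
    SVR: float          # relative to baseline (= 1 at rest)
    CO: float           # L/min
    RR: float
    UO: float           # mL/h, instantaneous
    pain: float         # 0-10
    epinephrine: float  # normalized elevation


def _cop_quadratic_coeff(patient: PatientConfig, k: ModelConstants) -> float:
    a2 = (patient.cop_mmhg - k.cop_linear * patient.albumin_g_l) / (
        patient.albumin_g_l ** 2
    )
    if a2 <= 0:
        raise ValueError("COP calibration requires a convex law; check baselines")
    return a2


def cop_from_albumin(
    albumin_g_l: float,
    patient: PatientConfig = PatientConfig(),
    constants: ModelConstants = ModelConstants(),
) -> float:
    """Colloid osmotic pressure (mmHg) from albumin concentration (g/L).

    Convex two-term law COP = a1 c + a2 c^2 with a2 fixed so the patient's
    baseline albumin maps to the baseline plasma COP.
    """
    if albumin_g_l < 0:
        raise ValueError("albumin concentration must be non-negative")
    a2 = _cop_quadratic_coeff(patient, constants)
    return constants.cop_linear * albumin_g_l + a2 * albumin_g_l ** 2


def _interstitial_albumin_baseline(
    patient: PatientConfig, k: ModelConstants
) -> float:
    """Interstitial albumin concentration whose COP matches the baseline."""
    a2 = _cop_quadratic_coeff(patient, k)
    a1 = k.cop_linear
    target = k.cop_interstitial_baseline
    # solve a2 c^2 + a1 c - target = 0 for c > 0
    return (-a1 + math.sqrt(a1 * a1 + 4 * a2 * target)) / (2 * a2)


def endothelium_from_damage(
    D: float, constants: ModelConstants = ModelConstants()
) -> EndothelialState:
    """Map tissue integrity D in [0, 1] to the barrier state.

    R_leak falls smoothly from baseline at D = 1 to a positive floor as damage
    accumulates; the albumin permeability-surface product rises from its
    baseline by up to ``perm_amplification``-fold.  Both maps are continuous
    and monotone and bounded away from pathological extremes.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"D must lie in [0, 1], got {D}")
    k = constants
    r = k.r_leak_baseline * (k.r_leak_floor + (1.0 - k.r_leak_floor) * D ** k.r_leak_power)
    ps0 = _baseline_permeability(PatientConfig(), k)
    ps = ps0 * (1.0 + k.perm_amplification * (1.0 - D) ** k.perm_power)
    return EndothelialState(R_leak=r, P_albumin=ps)


def _baseline_lymph_flow(patient: PatientConfig, k: ModelConstants) -> float:
    """Lymph return (L/h) that balances baseline filtration exactly."""
    cop_p0 = patient.cop_mmhg
    cop_i0 = k.cop_interstitial_baseline
    drive = (
        k.p_cap_baseline - k.p_int_baseline - k.sigma * (cop_p0 - cop_i0)
    )
    if drive <= 0:
        raise ValueError("baseline Starling forces must filter outward")
    return drive / k.r_leak_baseline


def _baseline_permeability(patient: PatientConfig, k: ModelConstants) -> float:
    """PS (L/h) that balances baseline albumin convection against lymph return."""
    L0 = _baseline_lymph_flow(patient, k)
    c_p0 = patient.albumin_g_l
    c_i0 = _interstitial_albumin_baseline(patient, k)
    ps0 = L0 * (c_i0 - (1.0 - k.sigma) * c_p0) / (c_p0 - c_i0)
    if ps0 <= 0:
        raise ValueError("baseline albumin balance infeasible; check constants")
    return ps0


def transcapillary_flux(
    state: HemodynamicState,
    endothelium: EndothelialState,
    patient: PatientConfig = PatientConfig(),
    constants: ModelConstants = ModelConstants(),
) -> Tuple[float, float]:
    """Starling fluid flux (L/h) and albumin flux (g/h), vascular -> interstitium.

    Fluid follows the net Starling pressure over the hydraulic resistance;
    albumin moves by convective drag (solvent drag with the 1 - sigma factor,
    upwind in the flow direction) plus permeability-driven diffusion.
    """
    k = constants
    vals = [state.MAP, state.COP_plasma, state.COP_interstitial, state.V_plasma]
    if not all(map(math.isfinite, vals)):
        raise ValueError("non-finite hemodynamic inputs")
    p_cap = k.p_cap_floor + (k.p_cap_baseline - k.p_cap_floor) * (
        state.MAP / patient.map_mmhg
    )
    p_int = k.p_int_baseline + k.interstitial_compliance * (
        state.V_interstitial - k.interstitial_volume_l
    )
    j_fluid = (
        p_cap - p_int - k.sigma * (state.COP_plasma - state.COP_interstitial)
    ) / endothelium.R_leak
    c_p = state.A_plasma / max(state.V_plasma, 1e-6)
    c_i = state.A_interstitial / max(state.V_interstitial, 1e-6)
    c_upwind = c_p if j_fluid >= 0 else c_i
    j_albumin = j_fluid * (1.0 - k.sigma) * c_upwind + endothelium.P_albumin * (
        c_p - c_i
    )
    return j_fluid, j_albumin


def baroreflex(
    MAP: float,
    setpoint: float,
    constants: ModelConstants = ModelConstants(),
) -> Tuple[float, float]:
    """Steady-state baroreflex targets (HR multiplier, SVR multiplier).

    Sigmoidal in the fractional pressure error, centred at the setpoint
    (multipliers 1 there) and saturating for large deficits: the reflex has a
    finite ceiling and is overwhelmed by severe hypotension.
    """
    if MAP <= 0:
        raise ValueError("MAP must be positive")
    err = (setpoint - MAP) / setpoint
    s = math.tanh(err / constants.baro_width)
    return 1.0 + constants.baro_gain_hr * s, 1.0 + constants.baro_gain_svr * s


def renal_output(
    MAP: float,
    V_plasma: float,
    patient: PatientConfig = PatientConfig(),
    constants: ModelConstants = ModelConstants(),
) -> float:
    """Urine output (mL/h): pressure-dependent filtration scaled by volume.

    Monotone increasing in both MAP and plasma volume, equal to the baseline
    UO at baseline inputs, and floored at zero below the anuric pressure.
    """
    k = constants
    p_frac = (MAP - k.renal_anuria_map) / (patient.map_mmhg - k.renal_anuria_map)
    p_frac = min(max(p_frac, 0.0), 1.0)  # autoregulation: no diuresis boost above baseline MAP
    v_frac = max(V_plasma / patient.plasma_volume_l, 0.0)
    return (
        patient.uo_ml_h
        * p_frac ** k.renal_pressure_exp
        * v_frac ** k.renal_volume_exp
    )


def pain_pathway(
    tbsa_fraction: float,
    analgesia_level: float = 0.0,
    constants: ModelConstants = ModelConstants(),
) -> Tuple[float, float, float]:
    """(pain score 0-10, epinephrine multiplier, RR multiplier) from burn size.

    Pain saturates at 10/10 for large burns and is divided down by analgesia
    (normalized ketamine effect-site level).  Epinephrine and respiration
    scale up with pain; no burn and no analgesia is exactly neutral.
    """
    if not 0.0 <= tbsa_fraction <= 1.0:
        raise ValueError("tbsa_fraction must lie in [0, 1]")
    if analgesia_level < 0:
        raise ValueError("analgesia level must be non-negative")
    k = constants
    pain = 10.0 * min(1.0, k.pain_tbsa_gain * tbsa_fraction)
    pain /= 1.0 + k.pain_analgesia_gain * analgesia_level
    epi = k.epi_pain_gain * pain / 10.0
    epi_mult = 1.0 + k.epi_hr_gain * epi
    rr_mult = 1.0 + k.rr_pain_gain * pain / 10.0
    return pain, epi_mult, rr_mult


# ---------------------------------------------------------------------------
# Coupled simulator
# ---------------------------------------------------------------------------

# full state vector layout: 8 inflammation states then the fluid/CV states
_IV, _II, _IU, _IAP, _IAI, _IHR, _ISVR, _IKET, _IINF = range(8, 17)
N_STATES = 17


class BurnSimulator:
    """Coupled inflammation + hemodynamics integrator for one patient.

    The full state vector stacks the eight inflammation states with plasma and
    interstitial volumes, cumulative urine, plasma and interstitial albumin,
    the baroreflex HR and SVR multipliers, the normalized ketamine effect-site
    level, and cumulative protocol fluid.  Integration uses a stiff-capable
    adaptive method (LSODA) piecewise between infusion-rate changes and drug
    boluses, so controller discontinuities never cross an integration segment.
    """

    def __init__(
        self,
        patient: PatientConfig = PatientConfig(),
        constants: ModelConstants = ModelConstants(),
        params: Optional[infl.InflammationParams] = None,
        rtol: float = 1e-7,
        atol: float = 1e-9,
    ) -> None:
        self.patient = patient
        self.constants = constants
        self.params = params or infl.InflammationParams()
        self.rtol = rtol
        self.atol = atol
        # derived baseline closure
        self.c_i0 = _interstitial_albumin_baseline(patient, constants)
        self.L0 = _baseline_lymph_flow(patient, constants)
        self.PS0 = _baseline_permeability(patient, constants)
        self.maintenance_l_h = (
            patient.uo_ml_h / 1000.0 if constants.maintenance_on else 0.0
        )

    # -- state construction -------------------------------------------------

    def initial_vector(self, tbsa_fraction: float) -> np.ndarray:
        y = np.zeros(N_STATES)
        y[:8] = infl.state_to_vector(infl.init_from_burn(tbsa_fraction))
        k = self.constants
        y[_IV] = self.patient.plasma_volume_l
        y[_II] = k.interstitial_volume_l
        y[_IAP] = self.patient.albumin_g_l * self.patient.plasma_volume_l
        y[_IAI] = self.c_i0 * k.interstitial_volume_l
        y[_IHR] = 1.0
        y[_ISVR] = 1.0
        return y

    def _endothelium(self, D: float) -> EndothelialState:
        k = self.constants
        r = k.r_leak_baseline * (
            k.r_leak_floor + (1.0 - k.r_leak_floor) * min(max(D, 0.0), 1.0) ** k.r_leak_power
        )
        ps = self.PS0 * (
            1.0 + k.perm_amplification * (1.0 - min(max(D, 0.0), 1.0)) ** k.perm_power
        )
        return EndothelialState(R_leak=r, P_albumin=ps)

    # -- observables --------------------------------------------------------

    def observables(self, y: np.ndarray) -> Dict[str, float]:
        """Algebraic outputs (MAP, HR, SVR, CO, RR, UO, COPs, pain, epi)."""
        p, k = self.patient, self.constants
        TR, NO, D = y[0], y[6], y[7]
        Vp = max(y[_IV], 1e-6)
        Vi = max(y[_II], 1e-6)
        ket = max(y[_IKET], 0.0)

        pain, _, rr_mult = pain_pathway(min(max(TR, 0.0), 1.0), ket, k)
        epi = k.epi_pain_gain * pain / 10.0 + k.ketamine_epi * ket

        c_p = y[_IAP] / Vp
        c_i = y[_IAI] / Vi
        cop_p = cop_from_albumin(max(c_p, 0.0), p, k)
        cop_i = cop_from_albumin(max(c_i, 0.0), p, k)

        vb = Vp + p.rbc_volume_l
        x = (vb - k.unstressed_blood_l) / (p.blood_volume_l - k.unstressed_blood_l)
        smooth = lambda z: 0.5 * (z + math.sqrt(z * z + k.sv_smoothing ** 2))
        sv_rel = smooth(x) / smooth(1.0)  # normalized so baseline is exactly 1

        hr_m = max(y[_IHR], 0.1)
        svr_m = max(y[_ISVR], 0.1)
        svr_eff = svr_m / (1.0 + k.no_vasodilation * NO)
        svr_eff *= 1.0 + k.ketamine_pressor * ket

        hr = p.hr_per_min * hr_m * (1.0 + k.epi_hr_gain * epi)
        co = k.co_baseline_l_min * (hr / p.hr_per_min) * sv_rel
        mapv = p.map_mmhg * (co / k.co_baseline_l_min) * svr_eff
        mapv = max(mapv, 1e-3)
        uo = renal_output(mapv, Vp, p, k)
        uo /= 1.0 + k.renal_epi_suppression * epi
        uo /= 1.0 + k.renal_damage_suppression * (1.0 - min(max(D, 0.0), 1.0))
        rr = p.rr_per_min * rr_mult

        return {
            "V_plasma": Vp,
            "V_interstitial": Vi,
            "V_blood": vb,
            "V_urine_cum": y[_IU],
            "V_infused_cum": y[_IINF],
            "A_plasma": y[_IAP],
            "A_interstitial": y[_IAI],
            "COP_plasma": cop_p,
            "COP_interstitial": cop_i,
            "MAP": mapv,
            "HR": hr,
            "SVR": svr_eff,
            "CO": co,
            "RR": rr,
            "UO": uo,
            "pain": pain,
            "epinephrine": epi,
            "ketamine": ket,
            "D": min(max(D, 0.0), 1.0),
            "TR": max(TR, 0.0),
        }

    def snapshot(self, y: np.ndarray) -> HemodynamicState:
        o = self.observables(y)
        return HemodynamicState(
            V_plasma=o["V_plasma"],
            V_interstitial=o["V_interstitial"],
            V_urine_cum=o["V_urine_cum"],
            A_plasma=o["A_plasma"],
            A_interstitial=o["A_interstitial"],
            COP_plasma=o["COP_plasma"],
            COP_interstitial=o["COP_interstitial"],
            MAP=o["MAP"],
            HR=o["HR"],
            SVR=o["SVR"],
            CO=o["CO"],
            RR=o["RR"],
            UO=o["UO"],
            pain=o["pain"],
            epinephrine=o["epinephrine"],
        )

    # -- dynamics -----------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, infusion_l_h: float = 0.0) -> np.ndarray:
        p, k = self.patient, self.constants
        dy = np.zeros_like(y)
        dy[:8] = infl._rhs(y[:8], self.params)

        o = self.observables(y)
        endo = self._endothelium(y[7])

        p_cap = k.p_cap_floor + (k.p_cap_baseline - k.p_cap_floor) * (
            o["MAP"] / p.map_mmhg
        )
        p_int = k.p_int_baseline + k.interstitial_compliance * (
            o["V_interstitial"] - k.interstitial_volume_l
        )
        j_fluid = (
            p_cap - p_int - k.sigma * (o["COP_plasma"] - o["COP_interstitial"])
        ) / endo.R_leak
        # capillary derecruitment: exchange shuts down as plasma volume empties
        # (normalized to 1 at the baseline plasma volume)
        vp = o["V_plasma"]
        cf = lambda v: v * v / (v * v + k.exchange_collapse_l ** 2)
        collapse = cf(vp) / cf(p.plasma_volume_l)
        j_fluid *= collapse
        c_p = o["A_plasma"] / o["V_plasma"]
        c_i = o["A_interstitial"] / o["V_interstitial"]
        c_up = c_p if j_fluid >= 0 else c_i
        j_alb = j_fluid * (1.0 - k.sigma) * c_up + collapse * endo.P_albumin * (
            c_p - c_i
        )

        lymph = self.L0 * max(o["V_interstitial"] / k.interstitial_volume_l, 0.0) ** k.lymph_exponent
        lymph_alb = lymph * c_i

        uo_l_h = o["UO"] / 1000.0
        evap = (
            k.evaporative_l_h_per_tbsa * o["TR"] if k.evaporative_loss_on else 0.0
        )

        dy[_IV] = -j_fluid + lymph + infusion_l_h + self.maintenance_l_h - uo_l_h
        dy[_II] = j_fluid - lymph - evap
        dy[_IU] = uo_l_h
        dy[_IAP] = -j_alb + lymph_alb
        dy[_IAI] = j_alb - lymph_alb

        hr_t, svr_t = baroreflex(o["MAP"], p.map_mmhg, k)
        epi = o["epinephrine"]
        hr_t *= 1.0 + k.epi_hr_gain * epi
        svr_t *= 1.0 + k.epi_svr_gain * epi
        dy[_IHR] = (hr_t - y[_IHR]) / k.baro_tau_h
        dy[_ISVR] = (svr_t - y[_ISVR]) / k.baro_tau_h

        dy[_IKET] = -k.ketamine_elimination * max(y[_IKET], 0.0)
        dy[_IINF] = infusion_l_h
        return dy

    def integrate_segment(
        self,
        y0: np.ndarray,
        t0: float,
        t1: float,
        infusion_l_h: float = 0.0,
        t_eval: Optional[np.ndarray] = None,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Integrate with a constant infusion rate over [t0, t1]."""
        sol = solve_ivp(
            self.rhs,
            (t0, t1),
            y0,
            args=(infusion_l_h,),
            method="LSODA",
            t_eval=t_eval,
            rtol=self.rtol,
            atol=self.atol,
            max_step=0.25,
        )
        if not sol.success:
            raise RuntimeError(
                f"hemodynamic integration failed on [{t0}, {t1}]: {sol.message}"
            )
        return sol.t, sol.y.T

    def run(
        self,
        tbsa_fraction: float,
        duration_h: float,
        infusion_schedule: Optional[Sequence[Tuple[float, float]]] = None,
        ketamine_boluses: Optional[Sequence[Tuple[float, float]]] = None,
        output_dt_h: float = 0.05,
    ) -> pd.DataFrame:
        """Simulate a burn scenario and return an hourly-and-finer time series.

        ``infusion_schedule`` is a list of (start_time_h, rate_ml_h) steps held
        constant until the next start time; ``ketamine_boluses`` is a list of
        (time_h, dose_mg).  Output columns are the observables plus time.
        """
        if duration_h <= 0:
            raise ValueError("duration_h must be positive")
        y = self.initial_vector(tbsa_fraction)
        schedule = sorted(infusion_schedule or [], key=lambda s: s[0])
        boluses = sorted(ketamine_boluses or [], key=lambda b: b[0])

        breaks = {0.0, duration_h}
        breaks.update(t for t, _ in schedule if 0.0 < t < duration_h)
        breaks.update(t for t, _ in boluses if 0.0 < t < duration_h)
        times = sorted(breaks)

        def rate_at(t: float) -> float:
            r = 0.0
            for ts, rate in schedule:
                if ts <= t:
                    r = rate
            return r / 1000.0

        for t, dose in boluses:
            if t == 0.0:
                y[_IKET] += dose / self.constants.ketamine_ref_dose_mg

        rows: List[Dict[str, float]] = []
        for t0, t1 in zip(times[:-1], times[1:]):
            n = max(2, int(round((t1 - t0) / output_dt_h)) + 1)
            t_eval = np.linspace(t0, t1, n)
            ts, ys = self.integrate_segment(y, t0, t1, rate_at(t0), t_eval)
            start = 1 if rows else 0  # avoid duplicating segment joints
            for t, yv in zip(ts[start:], ys[start:]):
                rec = self.observables(yv)
                rec["time_h"] = t
                rows.append(rec)
            y = ys[-1].copy()
            for tb, dose in boluses:
                if abs(tb - t1) < 1e-12:
                    y[_IKET] += dose / self.constants.ketamine_ref_dose_mg
        df = pd.DataFrame(rows)
        cols = ["time_h"] + [c for c in df.columns if c != "time_h"]
        return df[cols]


def advance(
    state: HemodynamicState,
    inflammation_state: infl.InflammationState,
    interventions: Optional[Dict[str, float]] = None,
    dt: float = 0.1,
    patient: PatientConfig = PatientConfig(),
    constants: ModelConstants = ModelConstants(),
) -> HemodynamicState:
    """Advance the fluid/cardiovascular state by ``dt`` hours.

    The inflammation state is held fixed over the step (use the coupled
    ``BurnSimulator.run`` for full scenarios).  ``interventions`` may contain
    ``infusion_ml_h`` and ``ketamine_level``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    iv = interventions or {}
    sim = BurnSimulator(patient, constants)
    y = sim.initial_vector(0.0)
    y[:8] = infl.state_to_vector(inflammation_state)
    y[_IV] = state.V_plasma
    y[_II] = state.V_interstitial
    y[_IU] = state.V_urine_cum
    y[_IAP] = state.A_plasma
    y[_IAI] = state.A_interstitial
    y[_IHR] = state.HR / patient.hr_per_min if state.HR > 0 else 1.0
    y[_ISVR] = state.SVR if state.SVR > 0 else 1.0
    y[_IKET] = iv.get("ketamine_level", 0.0)
    # freeze inflammation over the step
    frozen = infl.state_to_vector(inflammation_state)

    def rhs(t: float, yv: np.ndarray) -> np.ndarray:
        yv = yv.copy()
        yv[:8] = frozen
        dy = sim.rhs(t, yv, iv.get("infusion_ml_h", 0.0) / 1000.0)
        dy[:8] = 0.0
        return dy

    sol = solve_ivp(rhs, (0.0, dt), y, method="LSODA", rtol=1e-7, atol=1e-9)
    if not sol.success:
        raise RuntimeError(f"advance failed: {sol.message}")
    return sim.snapshot(sol.y[:, -1])
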