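"""Guideline burn fluid-resuscitation controller and drug actions.

The resuscitation protocol starts Lactated Ringer's at 10 x TBSA(%) mL/h and
titrates the rate up or down by 25% at every whole-hour mark to hold urine
output inside the 30-50 mL/h target band.  A 20 mg ketamine bolus manages
pain.  The Parkland formula (4 mL x kg x TBSA%, half in the first 8 h) is
provided as the textbook reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hemodynamics import BurnSimulator, ModelConstants, PatientConfig

__all__ = [
    "ProtocolState",
    "DrugBolus",
    "ProtocolResult",
    "UO_TARGET_LOW",
    "UO_TARGET_HIGH",
    "TITRATION_STEP",
    "initial_rate",
    "titrate",
    "parkland",
    "run_protocol",
    "apply_ketamine",
]

UO_TARGET_LOW = 30.0    # mL/h
UO_TARGET_HIGH = 50.0   # mL/h
TITRATION_STEP = 0.25   # fractional change per hourly decision


@dataclass(frozen=True)
class DrugBolus:
    drug: str
    dose_mg: float
    time_h: float

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")


@dataclass
class ProtocolState:
    """Running controller state: current rate, UO history, fluid bookkeeping."""

    current_rate_ml_h: float
    uo_history_ml_h: List[float] = field(default_factory=list)
    cumulative_infused_ml: float = 0.0
    uo_target_low: float = UO_TARGET_LOW
    uo_target_high: float = UO_TARGET_HIGH
    titration_step: float = TITRATION_STEP
    boluses: List[DrugBolus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.current_rate_ml_h < 0:
            raise ValueError("infusion rate must be non-negative")
        if not self.uo_target_low < self.uo_target_high:
            raise ValueError("UO target band must be a proper interval")


def initial_rate(tbsa_pct: float) -> float:
    """Starting LR rate in mL/h: 10 x TBSA percent."""
    if not 0.0 < tbsa_pct <= 100.0:
        raise ValueError(f"TBSA percent must lie in (0, 100], got {tbsa_pct}")
    return 10.0 * tbsa_pct


def titrate(
    rate_ml_h: float,
    last_hour_uo_ml_h: float,
    low: float = UO_TARGET_LOW,
    high: float = UO_TARGET_HIGH,
    step: float = TITRATION_STEP,
) -> float:
    """Hourly titration: x1.25 below the band, x0.75 above, hold inside.

    Band boundaries (exactly 30 or 50 mL/h) count as in range.
    """
    if rate_ml_h < 0 or last_hour_uo_ml_h < 0:
        raise ValueError("rate and urine output must be non-negative")
    if last_hour_uo_ml_h < low:
        return rate_ml_h * (1.0 + step)
    if last_hour_uo_ml_h > high:
        return rate_ml_h * (1.0 - step)
    return rate_ml_h


def parkland(mass_kg: float, tbsa_pct: float) -> Tuple[float, float]:
    """Parkland reference: (total 24 h mL, first-8-h mL) of crystalloid."""
    if mass_kg <= 0 or tbsa_pct <= 0:
        raise ValueError("mass and TBSA must be positive")
    total = 4.0 * mass_kg * tbsa_pct
    return total, total / 2.0


@dataclass
class ProtocolResult:
    """Coupled treated-run output: time series, decision log, final state."""

    timeseries: pd.DataFrame
    decisions: pd.DataFrame   # hour, mean UO, action, new rate, cumulative mL
    protocol: ProtocolState

    def cumulative_at(self, hour: float) -> float:
        """Cumulative infused volume (mL) at a given time, from the series."""
        df = self.timeseries
        return 1000.0 * float(np.interp(hour, df["time_h"], df["V_infused_cum"]))

    def hourly_uo(self) -> pd.Series:
        """Mean urine output (mL/h) over each whole simulated hour."""
        df = self.timeseries
        hours = np.arange(1, int(np.floor(df["time_h"].iloc[-1])) + 1)
        vu = np.interp(hours, df["time_h"], df["V_urine_cum"])
        vu0 = np.interp(hours - 1, df["time_h"], df["V_urine_cum"])
        return pd.Series(1000.0 * (vu - vu0), index=hours, name="uo_ml_h")

    def uo_recovery_hour(self) -> Optional[int]:
        """First whole hour whose mean UO is in band after a sub-band hour."""
        uo = self.hourly_uo()
        seen_low = False
        for h, v in uo.items():
            if v < UO_TARGET_LOW:
                seen_low = True
            elif seen_low and UO_TARGET_LOW <= v <= UO_TARGET_HIGH:
                return int(h)
        return None


def run_protocol(
    tbsa_pct: float,
    duration_h: float = 24.0,
    patient: PatientConfig = PatientConfig(),
    constants: ModelConstants = ModelConstants(),
    treat_start_h: float = 0.0,
    ketamine: Optional[Sequence[DrugBolus]] = None,
    simulator: Optional[BurnSimulator] = None,
) -> ProtocolResult:
    """Run the closed-loop resuscitation protocol against the coupled model.

    The controller observes the mean urine output over each completed hour and
    applies the 25% titration rule at whole-hour boundaries; the infusion rate
    is held constant in between, so every controller decision is an exact
    integration break.
    """
    if not 0.0 <= treat_start_h <= duration_h:
        raise ValueError("treatment start must lie within the run")
    sim = simulator or BurnSimulator(patient, constants)
    proto = ProtocolState(current_rate_ml_h=initial_rate(tbsa_pct))
    boluses = list(ketamine or [])

    y = sim.initial_vector(tbsa_pct / 100.0)
    for b in boluses:
        if b.time_h <= 0.0:
            y[15] += b.dose_mg / constants.ketamine_ref_dose_mg

    decisions: List[Dict[str, float]] = []
    vu_prev = 0.0
    hour_marks = np.arange(0.0, duration_h + 1e-9, 1.0)
    frames = []
    for t0, t1 in zip(hour_marks[:-1], hour_marks[1:]):
        rate = proto.current_rate_ml_h if t0 >= treat_start_h else 0.0
        t_eval = np.linspace(t0, t1, 21)
        ts, ys = sim.integrate_segment(y, t0, t1, rate / 1000.0, t_eval)
        recs = []
        for tt, yv in zip(ts, ys):
            rec = sim.observables(yv)
            rec["time_h"] = tt
            rec["infusion_ml_h"] = rate
            recs.append(rec)
        frames.append(pd.DataFrame(recs if not frames else recs[1:]))
        y = ys[-1].copy()
        proto.cumulative_infused_ml += rate * (t1 - t0)

        mean_uo = 1000.0 * (y[10] - vu_prev) / (t1 - t0)
        vu_prev = y[10]
        proto.uo_history_ml_h.append(mean_uo)

        action = "hold"
        if t1 >= treat_start_h and t1 < duration_h:
            new_rate = titrate(
                proto.current_rate_ml_h,
                mean_uo,
                proto.uo_target_low,
                proto.uo_target_high,
                proto.titration_step,
            )
            if new_rate > proto.current_rate_ml_h:
                action = "up 25%"
            elif new_rate < proto.current_rate_ml_h:
                action = "down 25%"
            proto.current_rate_ml_h = new_rate
        decisions.append(
            {
                "hour": t1,
                "mean_uo_ml_h": mean_uo,
                "action": action,
                "rate_next_ml_h": proto.current_rate_ml_h,
                "cumulative_ml": proto.cumulative_infused_ml,
            }
        )
        for b in boluses:
            if abs(b.time_h - t1) < 1e-9:
                y[15] += b.dose_mg / constants.ketamine_ref_dose_mg
        proto.boluses = boluses

    ts_df = pd.concat(frames, ignore_index=True)
    cols = ["time_h"] + [c for c in ts_df.columns if c != "time_h"]
    return ProtocolResult(
        timeseries=ts_df[cols],
        decisions=pd.DataFrame(decisions),
        protocol=proto,
    )


def apply_ketamine(
    tbsa_pct: float,
    dose_mg: float = 20.0,
    bolus_time_h: float = 1.0,
    duration_h: float = 6.0,
    patient: PatientConfig = PatientConfig(),
    constants: ModelConstants = ModelConstants(),
) -> Dict[str, pd.DataFrame]:
    """Twin runs with and without a ketamine bolus, for effect comparison.

    Ketamine depresses the pain signal (lowering respiration rate) and exerts
    a direct transient pressor effect (raising MAP) -- the latter reproduces
    the reference engine's behaviour in healthy subjects and is documented as
    questionable in burn patients, where sympathetic tone is already maximal.
    """
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    sim = BurnSimulator(patient, constants)
    untreated = sim.run(tbsa_pct / 100.0, duration_h)
    boluses = [(bolus_time_h, dose_mg)] if dose_mg > 0 else None
    treated = sim.run(tbsa_pct / 100.0, duration_h, ketamine_boluses=boluses)
    return {"untreated": untreated, "ketamine": treated}
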