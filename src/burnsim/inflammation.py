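"""Burn-triggered acute-inflammation kinetics.

A reduced whole-body model in the tradition of the Reynolds/Chow family of
acute-inflammation ODE systems, driven by thermal trauma instead of pathogen
load.  The burn size (fraction of total body surface area, TBSA) sets a trauma
stimulus TR that activates blood macrophages (M) and neutrophils (N); these
secrete the pro-inflammatory cytokines TNF and IL-6, which feed back on
activation, and drive production of nitric oxide (NO).  The anti-inflammatory
cytokine IL-10, produced downstream of IL-6, inhibits activation and cytokine
secretion.  Tissue/endothelial integrity D (1 = intact) is degraded by the
combined pro-inflammatory load and heals at a slow first-order rate.

For small burns the IL-10 arm checks the response and D stays near 1; large
burns saturate the anti-inflammatory arm so the pro-inflammatory response runs
disproportionately hot and D collapses.  That asymmetry, not any single rate
constant, is what the downstream hemodynamic behaviour is calibrated on.

All mediator levels are dimensionless elevations above healthy baseline
(healthy = 0); D and TR live on absolute 0-1 scales.  Time is in hours.
Infection/pathogen inputs are fixed at zero: this is sterile thermal injury.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InflammationState",
    "InflammationParams",
    "init_from_burn",
    "derivatives",
    "simulate_inflammation",
    "state_to_vector",
    "vector_to_state",
    "STATE_NAMES",
]

STATE_NAMES = ("TR", "M", "N", "TNF", "IL6", "IL10", "NO", "D")


@dataclass(frozen=True)
class InflammationState:
    """Mediator elevations (0 = healthy), trauma stimulus TR, integrity D."""

    TR: float = 0.0
    M: float = 0.0
    N: float = 0.0
    TNF: float = 0.0
    IL6: float = 0.0
    IL10: float = 0.0
    NO: float = 0.0
    D: float = 1.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES[:-1]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"D must lie in [0, 1], got {self.D}")


@dataclass(frozen=True)
class InflammationParams:
    """Rate constants, all in units of 1/h (production scales dimensionless).

    Defaults are calibrated so that the coupled hemodynamic model reproduces
    the reference burn trajectories: a compensated 10% TBSA burn, roughly one
    litre of plasma lost by hour 5 at 25%, and loss of half the vascular
    volume by hour 3 at 40%.
    """

    # trauma stimulus
    k_tr_decay: float = 0.02      # slow wound-driven stimulus decay
    # cell activation (Hill on combined stimulus, IL-10 inhibited)
    k_m: float = 2.0              # macrophage activation scale
    k_n: float = 2.5              # neutrophil activation scale
    c_tnf: float = 0.15           # TNF feedback weight in the stimulus
    K_act: float = 0.30           # half-saturation of activation stimulus
    h_act: float = 4.0            # activation Hill exponent (severity switch)
    K_inh: float = 0.5            # IL-10 inhibition constant
    d_m: float = 0.8
    d_n: float = 1.2
    # cytokines
    k_tnf: float = 1.8
    k_il6: float = 1.5
    K_inh6: float = 0.7
    d_tnf: float = 2.0
    d_il6: float = 1.0
    # anti-inflammatory arm (Michaelis-Menten in IL-6: proportionally strong
    # for small bursts, saturated -- overwhelmed -- for large ones)
    k_il10: float = 1.0
    K_il6_a: float = 0.5
    h_il6_a: float = 1.0
    d_il10: float = 0.4
    # nitric oxide
    k_no: float = 1.5
    d_no: float = 1.8
    # tissue integrity
    k_heal: float = 0.05
    k_dmg: float = 1.7
    K_dmg: float = 1.5
    h_dmg: float = 6.0
    w_tnf: float = 0.5
    w_n: float = 0.3
    w_tr: float = 0.4

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"parameter {f.name} must be positive")


def _hill(x: float, K: float, n: float) -> float:
    xn = max(x, 0.0) ** n
    return xn / (K ** n + xn)


def init_from_burn(tbsa_fraction: float) -> InflammationState:
    """Healthy baseline with the trauma stimulus set by the burn size.

    TR is taken equal to the TBSA fraction; all mediators start at baseline
    and integrity is intact (D = 1).  Infection states are identically zero.
    """
    if not 0.0 <= tbsa_fraction <= 1.0:
        raise ValueError(f"tbsa_fraction must lie in [0, 1], got {tbsa_fraction}")
    return InflammationState(TR=float(tbsa_fraction), D=1.0)


def derivatives(
    state: InflammationState, params: InflammationParams, t: float = 0.0
) -> Tuple[float, ...]:
    """Time derivatives of (TR, M, N, TNF, IL6, IL10, NO, D) in 1/h."""
    return _rhs(state_to_vector(state), params)


def _rhs(y: np.ndarray, p: InflammationParams) -> Tuple[float, ...]:
    TR, M, N, TNF, IL6, IL10, NO, D = (max(v, 0.0) for v in y[:8])
    D = min(D, 1.0)

    inh = 1.0 / (1.0 + (IL10 / p.K_inh) ** 2)
    inh6 = 1.0 / (1.0 + (IL10 / p.K_inh6) ** 2)
    stim = TR + p.c_tnf * TNF
    act = _hill(stim, p.K_act, p.h_act)

    dTR = -p.k_tr_decay * TR
    dM = p.k_m * act * inh - p.d_m * M
    dN = p.k_n * act * inh - p.d_n * N
    dTNF = p.k_tnf * (M + 0.5 * N) * inh - p.d_tnf * TNF
    dIL6 = p.k_il6 * (M + N) * inh6 - p.d_il6 * IL6
    dIL10 = p.k_il10 * _hill(IL6, p.K_il6_a, p.h_il6_a) - p.d_il10 * IL10
    dNO = p.k_no * (0.5 * N + TNF) - p.d_no * NO

    w = NO + p.w_tnf * TNF + p.w_n * N + p.w_tr * TR
    dD = p.k_heal * (1.0 - D) - p.k_dmg * D * _hill(w, p.K_dmg, p.h_dmg)
    return (dTR, dM, dN, dTNF, dIL6, dIL10, dNO, dD)


def state_to_vector(state: InflammationState) -> np.ndarray:
    return np.array([getattr(state, n) for n in STATE_NAMES], dtype=float)


def vector_to_state(y: np.ndarray) -> InflammationState:
    vals = {n: max(float(v), 0.0) for n, v in zip(STATE_NAMES, y)}
    vals["D"] = min(max(vals["D"], 0.0), 1.0)
    return InflammationState(**vals)


def simulate_inflammation(
    initial: InflammationState,
    params: InflammationParams = InflammationParams(),
    duration_h: float = 24.0,
    dt_h: float = 0.1,
    rtol: float = 1e-7,
    atol: float = 1e-9,
):
    """Integrate the inflammation system alone over ``duration_h`` hours.

    Returns (times, states) where states is an (n_times, 8) array in the
    order of ``STATE_NAMES``.  Uses a stiff-capable adaptive integrator and
    reports on a regular grid with spacing ``dt_h``.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    t_eval = np.arange(0.0, duration_h + 0.5 * dt_h, dt_h)
    sol = solve_ivp(
        lambda t, y: _rhs(y, params),
        (0.0, duration_h),
        state_to_vector(initial),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"inflammation integration failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    states[:, 7] = np.clip(states[:, 7], 0.0, 1.0)
    return sol.t, states
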