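"""Domain types and instantaneous physics of the closed-loop circulation.

The circulation is a lumped-parameter (zero-dimensional) network: four
heart chambers modeled as time-varying elastances, and systemic and
pulmonary vascular beds each reduced to a characteristic impedance (Rc),
an arterial resistance (Ra) with arterial compliance (Ca), and a venous
compliance (Cv) drained through a venous-return resistance (Rv).  Valves
are ideal diodes in series with a small resistance.  The conserved
quantity is the stressed blood volume distributed over eight
compartments.

Units are mm Hg, mL and s throughout; L/min appears only at reporting
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ChamberParams",
    "VascularBedParams",
    "CirculationParams",
    "LoopState",
    "COMPARTMENTS",
    "activation",
    "chamber_pressure",
    "flows",
    "rhs",
    "node_pressures",
]

#: Order of the state vector: ventricles, atria, then the four vascular
#: compartments (systemic arterial/venous, pulmonary arterial/venous).
COMPARTMENTS = ("lv", "rv", "la", "ra", "sa", "sv", "pa", "pv")

#: Order of the flow vector returned by :func:`flows`.
FLOW_EDGES = (
    "mitral",      # LA -> LV
    "aortic",      # LV -> systemic arterial (through valve + Rc)
    "systemic",    # systemic arterial -> systemic venous (through Ra)
    "venous_return",  # systemic venous -> RA
    "tricuspid",   # RA -> RV
    "pulmonic",    # RV -> pulmonary arterial (through valve + Rc)
    "pulmonary",   # pulmonary arterial -> pulmonary venous
    "pulm_venous_return",  # pulmonary venous -> LA
)


@dataclass(frozen=True)
class ChamberParams:
    """Time-varying elastance parameters of one heart chamber.

    The chamber interpolates between a linear end-systolic
    pressure-volume relation (ESPVR), ``P_es = ees * (V - v0)``, and an
    exponential end-diastolic relation (EDPVR),
    ``P_ed = beta * (exp(alpha * (V - v0)) - 1)``, through the
    activation function e(t) in [0, 1].

    Parameters
    ----------
    ees : float
        End-systolic elastance (ESPVR slope), mm Hg/mL.
    v0 : float
        Volume-axis intercept shared by ESPVR and EDPVR, mL.
    alpha : float
        EDPVR exponential rate constant, 1/mL.
    beta : float
        EDPVR pressure scale, mm Hg.
    tmax : float
        Time from activation onset to end-systole (peak elastance), s.
    tau : float
        Time constant of isovolumic relaxation, s.
    activation_delay : float
        Onset of activation relative to the start of the cycle, s.
    """

    ees: float
    v0: float
    alpha: float
    beta: float
    tmax: float
    tau: float
    activation_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.ees <= 0:
            raise ValueError(f"ees must be positive, got {self.ees}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.tmax <= 0:
            raise ValueError(f"tmax must be positive, got {self.tmax}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.activation_delay < 0:
            raise ValueError("activation_delay must be non-negative")


@dataclass(frozen=True)
class VascularBedParams:
    """Three-element Windkessel afterload plus a venous reservoir.

    Parameters
    ----------
    rc : float
        Characteristic impedance (proximal resistance between the
        ventricle and the arterial compliance), mm Hg*s/mL.
    ra : float
        Arterial (peripheral) resistance, mm Hg*s/mL.
    ca : float
        Arterial compliance, mL/mm Hg.
    cv : float
        Venous compliance, mL/mm Hg.
    rv : float
        Venous-return resistance draining the venous reservoir into the
        downstream atrium, mm Hg*s/mL.
    """

    rc: float
    ra: float
    ca: float
    cv: float
    rv: float

    def __post_init__(self) -> None:
        for name in ("rc", "ra", "ca", "cv", "rv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CirculationParams:
    """Full parameter set of the closed loop."""

    lv: ChamberParams
    rv: ChamberParams
    la: ChamberParams
    ra: ChamberParams
    systemic: VascularBedParams
    pulmonary: VascularBedParams
    hr: float                      # beats per minute
    stressed_blood_volume: float   # mL
    r_mitral: float = 0.005
    r_aortic: float = 0.005
    r_tricuspid: float = 0.005
    r_pulmonic: float = 0.005

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hr must be positive")
        if self.stressed_blood_volume <= 0:
            raise ValueError("stressed_blood_volume must be positive")
        for name in ("r_mitral", "r_aortic", "r_tricuspid", "r_pulmonic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for ch in (self.lv, self.rv, self.la, self.ra):
            if ch.tmax >= self.cycle_length:
                raise ValueError("chamber tmax must be shorter than the cycle")

    @property
    def cycle_length(self) -> float:
        """Cardiac cycle length 60/HR, s."""
        return 60.0 / self.hr

    def with_hr(self, hr: float) -> "CirculationParams":
        return replace(self, hr=hr)


@dataclass
class LoopState:
    """Instantaneous state: the eight compartment volumes and cycle time."""

    volumes: np.ndarray  # shape (8,), mL, ordered as COMPARTMENTS
    t: float = 0.0       # time within the cycle, s

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.shape != (len(COMPARTMENTS),):
            raise ValueError(f"expected {len(COMPARTMENTS)} volumes")
        if np.any(np.isnan(self.volumes)):
            raise ValueError("NaN in state volumes")
        if np.any(self.volumes < 0):
            raise ValueError("compartment volumes must be non-negative")

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())


def activation(t_in_cycle: float, params: ChamberParams, cycle_length: float) -> float:
    """Normalized activation e(t) in [0, 1] of a chamber.

    Two-phase form: a raised half-sine from activation onset to
    1.5*tmax (so that e = 1 exactly at t = activation_delay + tmax),
    followed by exponential relaxation with time constant tau.  Periodic
    in the cycle length.

    Raises
    ------
    ValueError
        If ``t_in_cycle`` is negative.
    """
    if t_in_cycle < 0:
        raise ValueError("time within cycle must be non-negative")
    tp = (t_in_cycle - params.activation_delay) % cycle_length
    ts = 1.5 * params.tmax
    if tp <= ts:
        return 0.5 * (math.sin(math.pi * tp / params.tmax - math.pi / 2.0) + 1.0)
    return 0.5 * math.exp(-(tp - ts) / params.tau)


def chamber_pressure(v: float, e: float, params: ChamberParams) -> float:
    """Instantaneous chamber pressure, mm Hg.

    ``P = e * P_es(V) + (1 - e) * P_ed(V)`` with linear ESPVR and
    exponential EDPVR; both relations vanish at ``v0``.
    """
    dv = v - params.v0
    p_es = params.ees * dv
    p_ed = params.beta * math.expm1(params.alpha * dv)
    return e * p_es + (1.0 - e) * p_ed


def node_pressures(
    state: LoopState,
    params: CirculationParams,
    p_dcc: float = 0.0,
) -> dict[str, float]:
    """Pressures of all eight compartments at the current state.

    The assist pressure ``p_dcc`` is added to both ventricles (and only
    the ventricles).  Vascular compartments are linear: P = V/C over
    stressed volume.
    """
    T = params.cycle_length
    v = state.volumes
    p = {}
    for i, (name, ch) in enumerate(
        zip(("lv", "rv", "la", "ra"), (params.lv, params.rv, params.la, params.ra))
    ):
        e = activation(state.t, ch, T)
        p[name] = chamber_pressure(v[i], e, ch)
    p["lv"] += p_dcc
    p["rv"] += p_dcc
    p["sa"] = v[4] / params.systemic.ca
    p["sv"] = v[5] / params.systemic.cv
    p["pa"] = v[6] / params.pulmonary.ca
    p["pv"] = v[7] / params.pulmonary.cv
    return p


def flows(
    state: LoopState,
    pressures: dict[str, float],
    params: CirculationParams,
) -> dict[str, float]:
    """Inter-compartment flows, mL/s.

    Resistor edges follow Ohm's law Q = dP/R; valve edges are ideal
    diodes, Q = max(0, dP)/R, so backflow is exactly zero.  The
    characteristic impedance of each bed is in series with the outflow
    valve.
    """
    p = pressures
    sys_, pul = params.systemic, params.pulmonary
    for r in (sys_.rc, sys_.ra, sys_.rv, pul.rc, pul.ra, pul.rv,
              params.r_mitral, params.r_aortic, params.r_tricuspid,
              params.r_pulmonic):
        if r <= 0:
            raise ValueError("resistances must be strictly positive")
    return {
        "mitral": max(0.0, p["la"] - p["lv"]) / params.r_mitral,
        "aortic": max(0.0, p["lv"] - p["sa"]) / (params.r_aortic + sys_.rc),
        "systemic": (p["sa"] - p["sv"]) / sys_.ra,
        "venous_return": (p["sv"] - p["ra"]) / sys_.rv,
        "tricuspid": max(0.0, p["ra"] - p["rv"]) / params.r_tricuspid,
        "pulmonic": max(0.0, p["rv"] - p["pa"]) / (params.r_pulmonic + pul.rc),
        "pulmonary": (p["pa"] - p["pv"]) / pul.ra,
        "pulm_venous_return": (p["pv"] - p["la"]) / pul.rv,
    }


def rhs(
    t: float,
    state: LoopState,
    params: CirculationParams,
    assist=None,
) -> np.ndarray:
    """Time derivative of the eight compartment volumes, mL/s.

    Pure volume bookkeeping over the network, so the components sum to
    zero exactly (closed loop).  With an assist waveform present the
    ventricular pressures used for the flow computation carry the
    epicardial compression term.
    """
    if np.any(np.isnan(state.volumes)):
        raise ValueError("NaN in state")
    p_dcc = 0.0
    if assist is not None and assist.enabled:
        from .dcc import dcc_pressure

        p_dcc = dcc_pressure(
            t % params.cycle_length, assist, params.cycle_length,
            onset=params.lv.activation_delay,
        )
    st = LoopState(state.volumes, t % params.cycle_length)
    p = node_pressures(st, params, p_dcc)
    q = flows(st, p, params)
    return np.array([
        q["mitral"] - q["aortic"],                 # LV
        q["tricuspid"] - q["pulmonic"],            # RV
        q["pulm_venous_return"] - q["mitral"],     # LA
        q["venous_return"] - q["tricuspid"],       # RA
        q["aortic"] - q["systemic"],               # systemic arterial
        q["systemic"] - q["venous_return"],        # systemic venous
        q["pulmonic"] - q["pulmonary"],            # pulmonary arterial
        q["pulmonary"] - q["pulm_venous_return"],  # pulmonary venous
    ])
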