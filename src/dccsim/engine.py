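"""Steady-state beat integration.

The closed loop is integrated with a fixed-step classical Runge-Kutta
scheme (nominal step 0.5 ms, adjusted so an integer number of steps
covers one cycle exactly).  Beats are integrated until the start-of-beat
compartment volumes change by less than a tolerance (default 0.05 mL)
from one beat to the next; the final full beat is returned as a
:class:`BeatTrace`.  The model is deterministic: the ``seed`` argument
is accepted for interface uniformity only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .dcc import DccSettings
from .model import COMPARTMENTS, ChamberParams, CirculationParams, LoopState

__all__ = ["BeatTrace", "run_to_steady_state", "pack_params", "initial_state"]

#: Nominal pressures (mm Hg) used only to shape the initial volume
#: distribution; any distribution converges to the same cycle.
_P_NOMINAL = {"sa": 45.0, "sv": 12.0, "pa": 18.0, "pv": 12.0}


def pack_params(params: CirculationParams, assist: DccSettings | None) -> np.ndarray:
    """Pack the parameter set into the kernel's flat vector."""
    mp = np.zeros(_kernel.NPARAM)
    for off, ch in zip(
        (_kernel.LV, _kernel.RV, _kernel.LA, _kernel.RA),
        (params.lv, params.rv, params.la, params.ra),
    ):
        mp[off: off + 7] = (ch.ees, ch.v0, ch.alpha, ch.beta,
                            ch.tmax, ch.tau, ch.activation_delay)
    for off, bed in ((_kernel.SYS, params.systemic), (_kernel.PUL, params.pulmonary)):
        mp[off: off + 5] = (bed.rc, bed.ra, bed.ca, bed.cv, bed.rv)
    T = params.cycle_length
    mp[_kernel.I_T] = T
    mp[_kernel.I_VALVES: _kernel.I_VALVES + 4] = (
        params.r_mitral, params.r_aortic, params.r_tricuspid, params.r_pulmonic)
    if assist is not None and assist.enabled:
        if assist.duration >= T:
            raise ValueError("assist trapezoid exceeds the cycle length")
        mp[_kernel.I_DCC] = 1.0
        mp[44:49] = (assist.amplitude, assist.offset, assist.rise_time,
                     assist.systolic_duration, assist.decline_time)
        mp[49] = (params.lv.activation_delay + assist.trigger_delay) % T
    return mp


def _passive_volume(ch: ChamberParams, p_fill: float) -> float:
    """Volume at which the passive (EDPVR) pressure equals ``p_fill``."""
    if ch.alpha <= 0 or ch.beta <= 0:
        return ch.v0 + p_fill  # degenerate linear fallback
    return ch.v0 + np.log1p(p_fill / ch.beta) / ch.alpha


def initial_state(params: CirculationParams) -> LoopState:
    """Distribute the stressed blood volume over the compartments.

    Chambers start at their passive-filling equilibrium for a nominal
    filling pressure; the remaining stressed volume is split over the
    vascular compartments proportionally to compliance-weighted nominal
    pressures.  Any distribution converges to the same periodic cycle;
    this one merely keeps the first transient beats well-behaved.
    """
    v = np.empty(8)
    for i, (ch, p_fill) in enumerate(zip(
            (params.lv, params.rv, params.la, params.ra),
            (10.0, 8.0, 8.0, 8.0))):
        v[i] = _passive_volume(ch, p_fill)
    rest = params.stressed_blood_volume - v[:4].sum()
    if rest <= 0:
        # tiny stressed volume: fall back to proportional scaling
        v[:4] *= 0.25 * params.stressed_blood_volume / v[:4].sum()
        rest = 0.75 * params.stressed_blood_volume
    w = np.array([
        params.systemic.ca * _P_NOMINAL["sa"],
        params.systemic.cv * _P_NOMINAL["sv"],
        params.pulmonary.ca * _P_NOMINAL["pa"],
        params.pulmonary.cv * _P_NOMINAL["pv"],
    ])
    v[4:] = rest * w / w.sum()
    return LoopState(v, 0.0)


def _activation_curve(t: np.ndarray, ch: ChamberParams, T: float) -> np.ndarray:
    tp = (t - ch.activation_delay) % T
    ts = 1.5 * ch.tmax
    rising = 0.5 * (np.sin(np.pi * tp / ch.tmax - np.pi / 2.0) + 1.0)
    decay = 0.5 * np.exp(-(tp - ts) / ch.tau)
    return np.where(tp <= ts, rising, decay)


def _dcc_curve(t: np.ndarray, assist: DccSettings | None,
               T: float, onset: float) -> np.ndarray:
    if assist is None or not assist.enabled:
        return np.zeros_like(t)
    tp = (t - onset - assist.trigger_delay) % T
    lo, hi = -assist.offset, assist.plateau
    p = np.full_like(t, lo)
    m = tp < assist.rise_time
    p[m] = lo + (hi - lo) * tp[m] / assist.rise_time
    m = (tp >= assist.rise_time) & (tp < assist.rise_time + assist.systolic_duration)
    p[m] = hi
    td = tp - assist.rise_time - assist.systolic_duration
    m = (td >= 0) & (td < assist.decline_time)
    p[m] = hi - (hi - lo) * td[m] / assist.decline_time
    return p


@dataclass
class BeatTrace:
    """Time-resolved signals over one periodic steady-state beat.

    ``volumes`` has one column per compartment in the order of
    :data:`dccsim.model.COMPARTMENTS`.  ``pressures`` holds the chamber
    pressures (assist included for LV/RV), the four vascular compartment
    pressures, and the catheter-site arterial pressures ``ao`` and
    ``pa_meas`` (compliance pressure plus the characteristic-impedance
    drop while the outflow valve conducts).
    """

    t: np.ndarray
    volumes: np.ndarray
    pressures: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    p_dcc: np.ndarray
    hr: float
    beats_to_converge: int
    steady_tol: float

    @property
    def cycle_length(self) -> float:
        return 60.0 / self.hr

    def volume(self, name: str) -> np.ndarray:
        return self.volumes[:, COMPARTMENTS.index(name)]

    def to_frame(self, decimate: int = 1) -> pd.DataFrame:
        """Tidy table: one row per time sample, one column per signal."""
        cols: dict[str, np.ndarray] = {"t_s": self.t}
        for i, name in enumerate(COMPARTMENTS):
            cols[f"v_{name}_ml"] = self.volumes[:, i]
        for name, arr in self.pressures.items():
            cols[f"p_{name}_mmhg"] = arr
        for name, arr in self.flows.items():
            cols[f"q_{name}_ml_s"] = arr
        cols["p_dcc_mmhg"] = self.p_dcc
        return pd.DataFrame(cols).iloc[:: max(1, int(decimate))].reset_index(drop=True)


def _signals(volumes: np.ndarray, params: CirculationParams,
             assist: DccSettings | None, nsteps: int):
    T = params.cycle_length
    t = np.linspace(0.0, T, nsteps + 1)
    p_dcc = _dcc_curve(t, assist, T, params.lv.activation_delay)
    p: dict[str, np.ndarray] = {}
    for i, (name, ch) in enumerate(zip(
            ("lv", "rv", "la", "ra"), (params.lv, params.rv, params.la, params.ra))):
        e = _activation_curve(t, ch, T)
        dv = volumes[:, i] - ch.v0
        p[name] = e * ch.ees * dv + (1.0 - e) * ch.beta * np.expm1(ch.alpha * dv)
    p["lv"] = p["lv"] + p_dcc
    p["rv"] = p["rv"] + p_dcc
    p["sa"] = volumes[:, 4] / params.systemic.ca
    p["sv"] = volumes[:, 5] / params.systemic.cv
    p["pa"] = volumes[:, 6] / params.pulmonary.ca
    p["pv"] = volumes[:, 7] / params.pulmonary.cv

    sys_, pul = params.systemic, params.pulmonary
    q = {
        "mitral": np.maximum(0.0, p["la"] - p["lv"]) / params.r_mitral,
        "aortic": np.maximum(0.0, p["lv"] - p["sa"]) / (params.r_aortic + sys_.rc),
        "systemic": (p["sa"] - p["sv"]) / sys_.ra,
        "venous_return": (p["sv"] - p["ra"]) / sys_.rv,
        "tricuspid": np.maximum(0.0, p["ra"] - p["rv"]) / params.r_tricuspid,
        "pulmonic": np.maximum(0.0, p["rv"] - p["pa"]) / (params.r_pulmonic + pul.rc),
        "pulmonary": (p["pa"] - p["pv"]) / pul.ra,
        "pulm_venous_return": (p["pv"] - p["la"]) / pul.rv,
    }
    # catheter-site arterial pressures: distal to the valve, proximal to Ca
    p["ao"] = p["sa"] + sys_.rc * q["aortic"]
    p["pa_meas"] = p["pa"] + pul.rc * q["pulmonic"]
    return t, p, q, p_dcc


def run_to_steady_state(
    params: CirculationParams,
    assist: DccSettings | None = None,
    init: LoopState | None = None,
    seed: int | None = None,
    dt: float = 5e-4,
    steady_tol: float = 0.05,
    max_beats: int = 200,
) -> BeatTrace:
    """Integrate the closed loop to its periodic steady state.

    Parameters
    ----------
    params : CirculationParams
    assist : DccSettings, optional
        Epicardial compression waveform; ``None`` or a disabled setting
        leaves the model untouched.
    init : LoopState, optional
        Starting volumes; defaults to :func:`initial_state`.
    seed : int, optional
        Unused (the model is deterministic); accepted for interface
        uniformity.
    dt : float
        Nominal integrator step, s; rounded so the cycle holds an
        integer number of steps.
    steady_tol : float
        Convergence tolerance on start-of-beat volumes, mL.
    max_beats : int
        Beat cap before a non-convergence error.

    Raises
    ------
    RuntimeError
        On non-convergence (naming the worst compartment) or a
        negative/non-finite volume.
    """
    del seed
    T = params.cycle_length
    nsteps = max(2, int(round(T / dt)))
    mp = pack_params(params, assist)
    state = init if init is not None else initial_state(params)
    v0 = np.asarray(state.volumes, dtype=float)
    if v0.shape != (8,) or np.any(~np.isfinite(v0)):
        raise ValueError("invalid initial state")
    # the integrator conserves total volume, so the start must carry
    # exactly the stressed blood volume of this parameter set
    v0 = v0 * (params.stressed_blood_volume / v0.sum())

    vstart, beats, worst, status = _kernel.integrate_to_steady(
        v0, mp, nsteps, max_beats, steady_tol)
    if status == 2:
        raise RuntimeError(
            f"compartment {COMPARTMENTS[worst]!r} volume became negative or "
            f"non-finite during beat {beats}")
    if status == 1:
        raise RuntimeError(
            f"no periodic steady state within {max_beats} beats; worst "
            f"compartment {COMPARTMENTS[worst]!r}")
    volumes, bad = _kernel.record_beat(vstart, mp, nsteps)
    if bad >= 0:
        raise RuntimeError(f"compartment {COMPARTMENTS[bad]!r} failed during recording")

    t, p, q, p_dcc = _signals(volumes, params, assist, nsteps)
    return BeatTrace(t=t, volumes=volumes, pressures=p, flows=q, p_dcc=p_dcc,
                     hr=params.hr, beats_to_converge=beats, steady_tol=steady_tol)
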