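"""Pressure-volume loop construction and ESPVR/EDPVR extraction.

The ESPVR sweep mimics a preload intervention in the closed loop by
rescaling the stressed blood volume (the zero-dimensional analog of a
vena-cava occlusion): the model is rerun to steady state at several
volume levels, end-systolic points are collected, and a line is fitted.
Under epicardial assist the fitted line keeps the chamber's slope and
shifts upward by the systolic plateau pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dcc import DccSettings
from .engine import BeatTrace, run_to_steady_state
from .metrics import HemodynamicSummary
from .model import ChamberParams, CirculationParams

__all__ = ["PVLoop", "PVRelation", "extract_loop", "end_systolic_point",
           "sweep_espvr", "edpvr_points", "sv_recovery"]


@dataclass(frozen=True)
class PVLoop:
    """One ventricular pressure-volume loop over a steady-state beat."""

    side: str            # "lv" or "rv"
    volume: np.ndarray   # mL
    pressure: np.ndarray  # mm Hg (assist included)
    edv: float
    esv: float
    sv: float
    sw: float            # stroke work, mm Hg*mL (area enclosed)
    pva: float           # pressure-volume area, mm Hg*mL


@dataclass(frozen=True)
class PVRelation:
    """A fitted end-systolic (linear) or configured end-diastolic relation."""

    kind: str                      # "ESPVR" | "EDPVR"
    slope: float | None = None     # ESPVR: mm Hg/mL
    offset: float | None = None    # ESPVR: pressure at V = v0, mm Hg
    alpha: float | None = None     # EDPVR
    beta: float | None = None
    v0: float | None = None
    points: np.ndarray | None = None  # (n, 2) volume, pressure samples used


def _ventricle(trace: BeatTrace, side: str) -> tuple[np.ndarray, np.ndarray]:
    side = side.lower()
    if side not in ("lv", "rv"):
        raise ValueError("side must be 'lv' or 'rv'")
    return trace.volume(side), trace.pressures[side]


def end_systolic_point(trace: BeatTrace, side: str,
                       chamber: ChamberParams) -> tuple[float, float]:
    """End-systolic (V, P) sample: the instant of maximal chamber
    elastance, located as the peak of P_chamber/(V - v0) with the
    epicardial assist term removed before forming the ratio.

    Robust under assist, where total peak pressure and minimal volume
    dissociate from peak elastance.  The returned pressure is the
    measured (assist-inclusive) ventricular pressure at that instant.
    Samples at volumes within 1 mL of v0 are excluded.
    """
    v, p = _ventricle(trace, side)
    native = p - trace.p_dcc
    dv = v - chamber.v0
    ratio = np.where(dv > 1.0, native / np.where(dv > 1.0, dv, 1.0), -np.inf)
    i = int(np.argmax(ratio))
    if not np.isfinite(ratio[i]):
        raise ValueError("no sample clear of v0 to define end-systole")
    return float(v[i]), float(p[i])


def extract_loop(trace: BeatTrace, side: str,
                 chamber: ChamberParams | None = None) -> PVLoop:
    """Build the PV loop of one ventricle from a steady-state trace.

    Stroke work is the enclosed (shoelace) area, positive for the
    physiologic traversal; the pressure-volume area adds the
    end-systolic triangle between the ESPVR volume intercept and the
    end-systolic point.  ``chamber`` (for the v0 reference) is required
    for the PVA; without it PVA is reported as NaN.
    """
    v, p = _ventricle(trace, side)
    gap = max(abs(v[0] - v[-1]), abs(p[0] - p[-1]))
    if gap > max(trace.steady_tol, 0.5):
        raise ValueError(f"PV trace is not closed (endpoint gap {gap:.3g})")
    edv = float(v.max())
    esv = float(v.min())
    # stroke work: -loop integral of P dV (ejection at high pressure)
    sw = -float(np.trapezoid(p, v))
    pva = float("nan")
    if chamber is not None:
        ves, pes = end_systolic_point(trace, side, chamber)
        pva = sw + 0.5 * (ves - chamber.v0) * pes
    return PVLoop(side=side.lower(), volume=v, pressure=p, edv=edv, esv=esv,
                  sv=edv - esv, sw=sw, pva=pva)


def _chamber_of(params: CirculationParams, side: str) -> ChamberParams:
    return params.lv if side.lower() == "lv" else params.rv


def sweep_espvr(
    params: CirculationParams,
    assist: DccSettings | None = None,
    side: str = "lv",
    n_loads: int = 5,
    spread: float = 0.2,
    **run_kwargs,
) -> PVRelation:
    """Fit the ESPVR from steady states at several preload levels.

    Stressed blood volume is scaled over ``1 +- spread`` in ``n_loads``
    steps; each level is run to steady state and its end-systolic point
    collected.  Returns the fitted line as slope and pressure offset at
    the chamber's volume intercept v0 (zero without assist, the assist
    plateau with it).
    """
    if n_loads < 3:
        raise ValueError("n_loads must be at least 3")
    chamber = _chamber_of(params, side)
    levels = np.linspace(1.0 - spread, 1.0 + spread, n_loads)
    pts = []
    for s in levels:
        p_s = replace(params,
                      stressed_blood_volume=s * params.stressed_blood_volume)
        trace = run_to_steady_state(p_s, assist=assist, **run_kwargs)
        pts.append(end_systolic_point(trace, side, chamber))
    pts = np.asarray(pts)
    x = pts[:, 0] - chamber.v0
    if np.ptp(x) < 1.0:
        raise ValueError("end-systolic volumes are degenerate; widen the sweep")
    slope, offset = np.polyfit(x, pts[:, 1], 1)
    return PVRelation(kind="ESPVR", slope=float(slope), offset=float(offset),
                      points=pts)


def edpvr_points(
    params: CirculationParams,
    assist: DccSettings | None = None,
    side: str = "lv",
    n_loads: int = 5,
    spread: float = 0.2,
    **run_kwargs,
) -> PVRelation:
    """End-diastolic (V, P) points over the same preload sweep.

    The configured chamber EDPVR parameters are attached so callers can
    check the points against the underlying exponential relation.
    """
    chamber = _chamber_of(params, side)
    levels = np.linspace(1.0 - spread, 1.0 + spread, max(3, n_loads))
    pts = []
    for s in levels:
        p_s = replace(params,
                      stressed_blood_volume=s * params.stressed_blood_volume)
        trace = run_to_steady_state(p_s, assist=assist, **run_kwargs)
        v, p = _ventricle(trace, side)
        i = int(np.argmax(v))
        pts.append((float(v[i]), float(p[i])))
    return PVRelation(kind="EDPVR", alpha=chamber.alpha, beta=chamber.beta,
                      v0=chamber.v0, points=np.asarray(pts))


def sv_recovery(baseline: HemodynamicSummary,
                assisted: HemodynamicSummary) -> float:
    """Percent recovery of baseline LV stroke volume under assist."""
    if baseline.lv_sv <= 0:
        raise ValueError("baseline stroke volume must be positive")
    return 100.0 * assisted.lv_sv / baseline.lv_sv
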