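"""Reduction of a steady-state beat to the standard hemodynamic panel.

Conventions: systolic/diastolic pressures are the extrema of the
catheter-site signal over the beat; mean pressures are beat averages by
trapezoidal quadrature; end-diastole is the instant of maximal
ventricular volume (robust to assist-induced timing shifts); PCWP is
proxied by mean pulmonary venous pressure and CVP by mean right atrial
pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .engine import BeatTrace

__all__ = ["HemodynamicSummary", "summarize", "PRESSURE_METRICS", "beat_mean"]

#: Pressure-valued metrics of the panel (the +-2 mm Hg fit criteria apply
#: to these).
PRESSURE_METRICS = ("sbp", "dbp", "map", "pasp", "padp", "mpap", "pcwp", "cvp")


@dataclass(frozen=True)
class HemodynamicSummary:
    """Scalar hemodynamic panel for one simulated state."""

    hr: float        # min^-1
    sbp: float       # mm Hg, aortic systolic
    dbp: float       # mm Hg, aortic diastolic
    map: float       # mm Hg, mean aortic
    pasp: float      # mm Hg
    padp: float      # mm Hg
    mpap: float      # mm Hg
    pcwp: float      # mm Hg
    cvp: float       # mm Hg
    lvedp: float     # mm Hg
    rvedp: float     # mm Hg
    lv_edv: float    # mL
    lv_esv: float    # mL
    rv_edv: float    # mL
    rv_esv: float    # mL
    lv_sv: float     # mL
    co: float        # L/min
    lvef: float      # %
    dpdt_max: float  # mm Hg/s

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def beat_mean(t: np.ndarray, x: np.ndarray) -> float:
    """Time average over one beat by trapezoidal quadrature."""
    return float(np.trapezoid(x, t) / (t[-1] - t[0]))


def summarize(trace: BeatTrace) -> HemodynamicSummary:
    """Compute the scalar panel from a periodic steady-state beat.

    Raises
    ------
    ValueError
        If the trace is not periodic to its steady-state tolerance.
    """
    drift = np.max(np.abs(trace.volumes[-1] - trace.volumes[0]))
    if drift > 2.0 * trace.steady_tol + 1e-9:
        raise ValueError(
            f"trace is not periodic (start/end volume gap {drift:.3g} mL)")
    t = trace.t
    p = trace.pressures
    v_lv = trace.volume("lv")
    v_rv = trace.volume("rv")

    i_edl = int(np.argmax(v_lv))
    i_edr = int(np.argmax(v_rv))
    lv_edv = float(v_lv[i_edl])
    lv_esv = float(v_lv.min())
    rv_edv = float(v_rv[i_edr])
    rv_esv = float(v_rv.min())
    lv_sv = lv_edv - lv_esv
    co = lv_sv * trace.hr / 1000.0
    return HemodynamicSummary(
        hr=trace.hr,
        sbp=float(p["ao"].max()),
        dbp=float(p["ao"].min()),
        map=beat_mean(t, p["ao"]),
        pasp=float(p["pa_meas"].max()),
        padp=float(p["pa_meas"].min()),
        mpap=beat_mean(t, p["pa_meas"]),
        pcwp=beat_mean(t, p["pv"]),
        cvp=beat_mean(t, p["ra"]),
        lvedp=float(p["lv"][i_edl]),
        rvedp=float(p["rv"][i_edr]),
        lv_edv=lv_edv,
        lv_esv=lv_esv,
        rv_edv=rv_edv,
        rv_esv=rv_esv,
        lv_sv=lv_sv,
        co=co,
        lvef=100.0 * lv_sv / lv_edv,
        dpdt_max=float(np.max(np.gradient(p["lv"], t))),
    )
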