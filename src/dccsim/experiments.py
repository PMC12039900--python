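"""The validation protocol: calibrated baseline and heart-failure
states, assist switched on from the unassisted steady state, effect
sizes, stroke-volume recovery and ESPVR shifts.

This module strings the library together exactly the way the in-vivo
protocol was structured: fit the model to the mean baseline and HF
hemodynamic profiles, predict the effect of compression assist at the
19 and 30 mm Hg plateau settings, and reduce the paired runs to the
standard effect panel.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibrate import FitResult, FitTargets, calibrate
from .config import load_targets
from .dcc import DccSettings, preset
from .engine import BeatTrace, run_to_steady_state
from .metrics import HemodynamicSummary, summarize
from .model import CirculationParams, LoopState
from .pv import PVRelation, sv_recovery, sweep_espvr
from .stats import EffectSummary, delta

__all__ = ["ValidationResult", "run_validation_experiment",
           "assisted_steady_state"]


def assisted_steady_state(params: CirculationParams, assist: DccSettings,
                          hf_trace: BeatTrace | None = None,
                          **run_kwargs) -> BeatTrace:
    """Steady state with the device on, started from the unassisted one.

    Turning assist on from the already-converged unassisted cycle
    mirrors device activation in the animal protocol and avoids the
    large cold-start transients of an arbitrary volume distribution.
    """
    init = None
    if hf_trace is not None:
        init = LoopState(hf_trace.volumes[-1], 0.0)
    return run_to_steady_state(params, assist=assist, init=init, **run_kwargs)


@dataclass
class ValidationResult:
    """Everything the mean-level validation study produces."""

    baseline_fit: FitResult
    hf_fit: FitResult
    hf: HemodynamicSummary
    hf_dcc19: HemodynamicSummary
    hf_dcc30: HemodynamicSummary
    effect19: EffectSummary          # HF+DCC19 minus HF
    effect30: EffectSummary
    recovery19_pct: float            # % of baseline LV stroke volume
    recovery30_pct: float
    espvr_unassisted: PVRelation
    espvr_dcc19: PVRelation
    espvr_dcc30: PVRelation
    max_pressure_error: float        # worst |achieved - target|, HF fit


def run_validation_experiment(
    seed: int = 0,
    baseline_targets: FitTargets | None = None,
    hf_targets: FitTargets | None = None,
    dt: float = 5e-4,
    sweep_loads: int = 5,
    restarts: int = 3,
) -> ValidationResult:
    """Calibrate to the mean profiles and predict the assist effects.

    Deterministic for a given seed.  Raises if either calibration ends
    without an accepted fit.
    """
    from .presets import ovine_base

    bl_t = baseline_targets or load_targets("baseline_mean")
    hf_t = hf_targets or load_targets("hf_mean")

    bl_fit = calibrate(bl_t, ovine_base(bl_t.hr), seed=seed, dt=dt,
                       restarts=restarts)
    hf_fit = calibrate(hf_t, ovine_base(hf_t.hr), seed=seed, dt=dt,
                       restarts=restarts)
    for name, fit in (("baseline", bl_fit), ("hf", hf_fit)):
        if not fit.accepted:
            bad = [m for m, r in fit.report.items() if not r["pass"]]
            raise RuntimeError(
                f"{name} calibration not accepted (failing: {bad})")

    hf_trace = run_to_steady_state(hf_fit.params, dt=dt)
    s_hf = summarize(hf_trace)

    tmax = hf_fit.params.lv.tmax
    a19 = preset("dcc19", tmax=tmax)
    a30 = preset("dcc30", tmax=tmax)
    s19 = summarize(assisted_steady_state(hf_fit.params, a19, hf_trace, dt=dt))
    s30 = summarize(assisted_steady_state(hf_fit.params, a30, hf_trace, dt=dt))

    warm = LoopState(hf_trace.volumes[-1], 0.0)
    rel0 = sweep_espvr(hf_fit.params, side="lv", n_loads=sweep_loads,
                       init=warm, dt=dt)
    rel19 = sweep_espvr(hf_fit.params, assist=a19, side="lv",
                        n_loads=sweep_loads, init=warm, dt=dt)
    rel30 = sweep_espvr(hf_fit.params, assist=a30, side="lv",
                        n_loads=sweep_loads, init=warm, dt=dt)

    from .metrics import PRESSURE_METRICS

    worst = max(abs(hf_fit.report[m]["error"]) for m in PRESSURE_METRICS)

    return ValidationResult(
        baseline_fit=bl_fit, hf_fit=hf_fit, hf=s_hf,
        hf_dcc19=s19, hf_dcc30=s30,
        effect19=delta(s_hf, s19, "dcc19"),
        effect30=delta(s_hf, s30, "dcc30"),
        recovery19_pct=sv_recovery(bl_fit.achieved, s19),
        recovery30_pct=sv_recovery(bl_fit.achieved, s30),
        espvr_unassisted=rel0, espvr_dcc19=rel19, espvr_dcc30=rel30,
        max_pressure_error=worst,
    )
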