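"""Calibration of the closed loop to a hemodynamic target profile.

The fitting protocol mirrors standard practice with lumped-parameter
models: heart rate is copied from the targets, a chosen set of free
parameters (stressed blood volume, afterload elements, chamber
elastances, timing constants) is adjusted by bounded least squares on
log-transformed values until the simulated steady-state panel matches
the targets, and the fit is accepted only if every pressure is within
+-2 mm Hg of its target (inclusive) with equivalent circulation metrics
(cardiac output within 0.05 L/min, ejection fraction within 2
percentage points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.optimize import least_squares

from .engine import run_to_steady_state
from .metrics import PRESSURE_METRICS, HemodynamicSummary, summarize
from .model import CirculationParams, LoopState

__all__ = [
    "FitTargets", "FitResult", "calibrate", "check_acceptance",
    "FREE_PARAM_NAMES", "DEFAULT_FREE_PARAMS",
]

log = logging.getLogger(__name__)

#: Fit tolerances: pressures +-2 mm Hg (inclusive); CO within 0.05 L/min
#: and LVEF within 2 percentage points ("equivalent circulation
#: metrics"); HR is copied into the model so it must match exactly.
PRESSURE_TOL = 2.0
CO_TOL = 0.05
LVEF_TOL = 2.0


@dataclass(frozen=True)
class FitTargets:
    """Target hemodynamic profile (the simulator's key inputs)."""

    hr: float
    lvef: float
    co: float
    cvp: float
    pcwp: float
    pasp: float
    padp: float
    mpap: float
    sbp: float
    dbp: float
    map: float
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "weights":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"target {f.name} must be positive")
        if self.sbp < self.dbp or self.pasp < self.padp:
            raise ValueError("systolic targets must be >= diastolic targets")

    def metric_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self) if f.name != "weights")


@dataclass
class FitResult:
    """Outcome of one calibration."""

    params: CirculationParams
    achieved: HemodynamicSummary
    residuals: dict[str, float]       # achieved - target, per metric
    accepted: bool
    iterations: int
    report: dict[str, dict] = field(default_factory=dict)


def check_acceptance(
    targets: FitTargets, achieved: HemodynamicSummary
) -> tuple[bool, dict[str, dict]]:
    """Per-metric fit verdicts against the acceptance tolerances.

    Every pressure target must be within +-2 mm Hg (bound inclusive);
    CO within 0.05 L/min, LVEF within 2 percentage points, HR exact.
    Returns the overall verdict and one entry per supplied target.
    """
    tols = {"co": CO_TOL, "lvef": LVEF_TOL, "hr": 1e-6}
    tols.update({m: PRESSURE_TOL for m in PRESSURE_METRICS})
    report: dict[str, dict] = {}
    ok = True
    for name in targets.metric_names():
        tgt = getattr(targets, name)
        ach = getattr(achieved, name)
        err = ach - tgt
        passed = abs(err) <= tols[name] + 1e-9  # inclusive bound

        ok &= passed
        report[name] = {"target": tgt, "achieved": ach, "error": err,
                        "tol": tols[name], "pass": passed}
    return ok, report


# ---------------------------------------------------------------------------
# free-parameter plumbing

def _set_bed(params, bed_name, field_name, value):
    bed = replace(getattr(params, bed_name), **{field_name: value})
    return replace(params, **{bed_name: bed})


def _set_chamber(params, ch_name, field_name, value):
    ch = replace(getattr(params, ch_name), **{field_name: value})
    return replace(params, **{ch_name: ch})


def _set_vent_timing(params, field_name, value):
    p = _set_chamber(params, "lv", field_name, value)
    return _set_chamber(p, "rv", field_name, value)


_SETTERS = {
    "sbv": lambda p, x: replace(p, stressed_blood_volume=x),
    "ra_sys": lambda p, x: _set_bed(p, "systemic", "ra", x),
    "rc_sys": lambda p, x: _set_bed(p, "systemic", "rc", x),
    "ca_sys": lambda p, x: _set_bed(p, "systemic", "ca", x),
    "ra_pulm": lambda p, x: _set_bed(p, "pulmonary", "ra", x),
    "rc_pulm": lambda p, x: _set_bed(p, "pulmonary", "rc", x),
    "ca_pulm": lambda p, x: _set_bed(p, "pulmonary", "ca", x),
    "ees_lv": lambda p, x: _set_chamber(p, "lv", "ees", x),
    "ees_rv": lambda p, x: _set_chamber(p, "rv", "ees", x),
    "ees_la": lambda p, x: _set_chamber(p, "la", "ees", x),
    "ees_ra": lambda p, x: _set_chamber(p, "ra", "ees", x),
    "tmax": lambda p, x: _set_vent_timing(p, "tmax", x),
    "tau": lambda p, x: _set_vent_timing(p, "tau", x),
}

_GETTERS = {
    "sbv": lambda p: p.stressed_blood_volume,
    "ra_sys": lambda p: p.systemic.ra,
    "rc_sys": lambda p: p.systemic.rc,
    "ca_sys": lambda p: p.systemic.ca,
    "ra_pulm": lambda p: p.pulmonary.ra,
    "rc_pulm": lambda p: p.pulmonary.rc,
    "ca_pulm": lambda p: p.pulmonary.ca,
    "ees_lv": lambda p: p.lv.ees,
    "ees_rv": lambda p: p.rv.ees,
    "ees_la": lambda p: p.la.ees,
    "ees_ra": lambda p: p.ra.ees,
    "tmax": lambda p: p.lv.tmax,
    "tau": lambda p: p.lv.tau,
}

_BOUNDS = {
    "sbv": (150.0, 3000.0),
    "ra_sys": (0.1, 5.0),
    "rc_sys": (0.004, 0.4),
    "ca_sys": (0.2, 10.0),
    "ra_pulm": (0.008, 1.5),
    "rc_pulm": (0.002, 0.3),
    "ca_pulm": (0.3, 25.0),
    "ees_lv": (0.3, 12.0),
    "ees_rv": (0.5, 10.0),
    "ees_la": (0.05, 5.0),
    "ees_ra": (0.05, 5.0),
    "tmax": (0.15, 0.42),
    "tau": (0.015, 0.12),
}

FREE_PARAM_NAMES = tuple(_SETTERS)

#: The set freed by default: stressed volume, both afterloads, the
#: chamber elastances and the ventricular timing constants.
DEFAULT_FREE_PARAMS = (
    "sbv", "ra_sys", "rc_sys", "ca_sys", "ra_pulm", "rc_pulm", "ca_pulm",
    "ees_lv", "ees_rv", "ees_la", "ees_ra", "tmax", "tau",
)

#: Residual weights, one per unit of fitting tolerance.
_WEIGHTS = {"co": 1.0 / CO_TOL, "lvef": 1.0 / LVEF_TOL}
_WEIGHTS.update({m: 1.0 / PRESSURE_TOL for m in PRESSURE_METRICS})
_FIT_METRICS = tuple(_WEIGHTS)


def _apply(params: CirculationParams, free: tuple[str, ...], values) -> CirculationParams:
    for name, v in zip(free, values):
        params = _SETTERS[name](params, float(v))
    return params


def initial_guess(targets: FitTargets, base: CirculationParams,
                  free: tuple[str, ...]) -> CirculationParams:
    """Analytic warm start from the targets.

    Resistances come from mean pressure drops over cardiac output,
    compliances from stroke volume over pulse pressure, and ventricular
    elastances from end-systolic pressure over the target end-systolic
    volume.  Only parameters in ``free`` are touched.
    """
    from .engine import _passive_volume

    q = targets.co * 1000.0 / 60.0          # mL/s
    sv = targets.co * 1000.0 / targets.hr   # mL
    edv = sv / (targets.lvef / 100.0)
    esv = edv - sv
    # RV end-diastolic volume from the passive filling curve at ~CVP
    rv_edv = _passive_volume(base.rv, targets.cvp)
    guesses = {
        "ra_sys": 0.93 * (targets.map - targets.cvp) / q,
        "rc_sys": 0.05 * (targets.map - targets.cvp) / q,
        "ca_sys": sv / max(targets.sbp - targets.dbp, 1.0),
        "ra_pulm": max((targets.mpap - targets.pcwp) / q, 0.015),
        "rc_pulm": 0.008,
        "ca_pulm": sv / max(targets.pasp - targets.padp, 1.0),
        "ees_lv": 0.9 * targets.sbp / max(esv - base.lv.v0, 5.0),
        # mean-ejection pressure (~PASP/2) over the end-systolic excursion
        "ees_rv": 0.5 * targets.pasp / max(rv_edv - sv - base.rv.v0, 4.0),
    }
    clipped = {}
    for name in free:
        if name in guesses:
            lo, hi = _BOUNDS[name]
            clipped[name] = float(np.clip(guesses[name], lo, hi))
    return _apply(base, tuple(clipped), clipped.values())


def calibrate(
    targets: FitTargets,
    base: CirculationParams,
    free_params: tuple[str, ...] = DEFAULT_FREE_PARAMS,
    seed: int = 0,
    restarts: int = 3,
    dt: float = 5e-4,
    steady_tol: float = 0.02,
    max_nfev: int = 60,
    warm_start: bool = True,
) -> FitResult:
    """Fit the model to a target profile.

    Heart rate is copied from the targets; the remaining free
    parameters are optimized by bounded least squares on their
    logarithms (positivity by construction), with up to ``restarts``
    seeded perturbed restarts if the first solution is not accepted.
    Deterministic for a given seed.  An unreachable target set returns
    ``accepted=False`` rather than raising.
    """
    unknown = set(free_params) - set(FREE_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    free = tuple(free_params)
    base = base.with_hr(targets.hr)
    start = initial_guess(targets, base, free) if warm_start else base

    weights = dict(_WEIGHTS)
    if targets.weights:
        weights.update(targets.weights)

    state_cache: dict[str, LoopState | None] = {"init": None}
    nfev = 0

    def simulate(params: CirculationParams) -> HemodynamicSummary:
        nonlocal nfev
        init = state_cache["init"]
        if init is not None:
            vols = init.volumes * (params.stressed_blood_volume / init.total_volume)
            init = LoopState(vols, 0.0)
        trace = run_to_steady_state(params, init=init, dt=dt,
                                    steady_tol=steady_tol)
        state_cache["init"] = LoopState(trace.volumes[-1], 0.0)
        nfev += 1
        return summarize(trace)

    def residuals_of(ach: HemodynamicSummary) -> np.ndarray:
        return np.array([
            weights[m] * (getattr(ach, m) - getattr(targets, m))
            for m in _FIT_METRICS
        ])

    def objective(x: np.ndarray) -> np.ndarray:
        params = _apply(base, free, np.exp(x))
        try:
            return residuals_of(simulate(params))
        except RuntimeError as exc:  # divergent corner of parameter space
            log.debug("simulation failed during fit: %s", exc)
            state_cache["init"] = None  # drop the poisoned warm start
            return np.full(len(_FIT_METRICS), 1e3)

    lb = np.log([_BOUNDS[n][0] for n in free])
    ub = np.log([_BOUNDS[n][1] for n in free])
    x0 = np.log(np.clip([_GETTERS[n](start) for n in free],
                        np.exp(lb), np.exp(ub)))

    # deterministic attempt schedule first: the plain analytic guess,
    # then variants with a progressively stronger atrial kick (profiles
    # with high output at low venous pressure need it to fill the
    # ventricles) and a softer RV; seeded random jitter only after.
    def _scaled(factors: dict[str, float]) -> np.ndarray:
        x = x0.copy()
        for name, f in factors.items():
            if name in free:
                i = free.index(name)
                x[i] = np.clip(x[i] + np.log(f), lb[i], ub[i])
        return x

    schedule = [x0,
                _scaled({"ees_ra": 3.0, "ees_la": 2.0}),
                _scaled({"ees_ra": 6.0, "ees_la": 3.0}),
                _scaled({"ees_rv": 0.6})]

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(len(schedule) + max(0, restarts)):
        xi = schedule[attempt] if attempt < len(schedule) else np.clip(
            x0 + rng.normal(0.0, 0.3, size=x0.size), lb, ub)
        sol = least_squares(objective, xi, bounds=(lb, ub), method="trf",
                            diff_step=5e-3, max_nfev=max_nfev)
        fitted = _apply(base, free, np.exp(sol.x))
        try:
            state_cache["init"] = None  # judge the fit from a cold start
            achieved = simulate(fitted)
        except RuntimeError as exc:
            log.info("calibration attempt %d: solution not simulable (%s)",
                     attempt, exc)
            continue
        accepted, report = check_acceptance(targets, achieved)
        resid = {m: getattr(achieved, m) - getattr(targets, m)
                 for m in _FIT_METRICS}
        result = FitResult(params=fitted, achieved=achieved, residuals=resid,
                           accepted=accepted, iterations=nfev, report=report)
        log.info("calibration attempt %d: cost=%.3g accepted=%s",
                 attempt, float(sol.cost), accepted)
        if accepted:
            return result
        if best is None or sum(r * r for r in resid.values()) < \
                sum(r * r for r in best.residuals.values()):
            best = result
    if best is None:
        raise RuntimeError("calibration failed: no simulable solution found")
    return best
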