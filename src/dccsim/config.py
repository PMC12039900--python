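"""Configuration schema, fixtures and scenario runner.

Scenario files are YAML with units spelled out in every key name
(``ees_mmhg_per_ml``, ``tau_s``, ...) because unit mistakes are the
dominant failure mode in hemodynamic modelling.  A scenario supplies
either an explicit circulation parameter set or calibration targets
plus a base parameter set — never both — and optionally an assist
waveform (by preset name or explicit block).  Unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .calibrate import DEFAULT_FREE_PARAMS, FitTargets, calibrate
from .dcc import DccSettings, preset
from .engine import run_to_steady_state
from .metrics import summarize
from .model import ChamberParams, CirculationParams, VascularBedParams
from .pv import extract_loop

__all__ = [
    "ScenarioConfig", "load_scenario", "run_scenario",
    "load_targets", "load_params", "save_params", "list_fixtures",
    "fixture_path", "params_to_doc", "doc_to_params", "load_cohort",
]

#: maps the unit-suffixed document keys onto panel metric names
_DOC_TO_METRIC = {
    "hr_per_min": "hr", "lvef_pct": "lvef", "co_l_per_min": "co",
    "cvp_mmhg": "cvp", "pcwp_mmhg": "pcwp", "pasp_mmhg": "pasp",
    "padp_mmhg": "padp", "mpap_mmhg": "mpap", "sbp_mmhg": "sbp",
    "dbp_mmhg": "dbp", "map_mmhg": "map",
}

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChamberDoc(_Strict):
    ees_mmhg_per_ml: float
    v0_ml: float
    alpha_per_ml: float
    beta_mmhg: float
    tmax_s: float
    tau_s: float
    activation_delay_s: float = 0.0


class BedDoc(_Strict):
    rc_mmhg_s_per_ml: float
    ra_mmhg_s_per_ml: float
    ca_ml_per_mmhg: float
    cv_ml_per_mmhg: float
    rv_mmhg_s_per_ml: float


class ValvesDoc(_Strict):
    mitral_mmhg_s_per_ml: float = 0.005
    aortic_mmhg_s_per_ml: float = 0.005
    tricuspid_mmhg_s_per_ml: float = 0.005
    pulmonic_mmhg_s_per_ml: float = 0.005


class CirculationDoc(_Strict):
    hr_per_min: float
    stressed_blood_volume_ml: float
    lv: ChamberDoc
    rv: ChamberDoc
    la: ChamberDoc
    ra: ChamberDoc
    systemic: BedDoc
    pulmonary: BedDoc
    valves: ValvesDoc = ValvesDoc()


class TargetsDoc(_Strict):
    hr_per_min: float
    lvef_pct: float
    co_l_per_min: float
    cvp_mmhg: float
    pcwp_mmhg: float
    pasp_mmhg: float
    padp_mmhg: float
    mpap_mmhg: float
    sbp_mmhg: float
    dbp_mmhg: float
    map_mmhg: float
    sd: dict[str, float] | None = None   # optional per-metric SDs (cohorts)


class DccDoc(_Strict):
    amplitude_mmhg: float
    offset_mmhg: float = 4.0
    rise_time_s: float = 0.10
    decline_time_s: float = 0.05
    systolic_duration_s: float | None = None  # None: end decline at 1.5*tmax
    trigger_delay_s: float = 0.02
    enabled: bool = True


class EngineDoc(_Strict):
    dt_s: float = 5e-4
    steady_tol_ml: float = 0.05
    max_beats: int = 200


class ScenarioConfig(_Strict):
    """Validated description of one simulation scenario."""

    schema_version: int = SCHEMA_VERSION
    label: str = "scenario"
    params: CirculationDoc | None = None
    targets: TargetsDoc | None = None
    base: str | CirculationDoc | None = None  # fixture name or inline params
    free_params: list[str] | None = None
    assist: str | DccDoc | None = None
    engine: EngineDoc = EngineDoc()
    seed: int = 0
    decimate: int = 1

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "ScenarioConfig":
        if (self.params is None) == (self.targets is None):
            raise ValueError(
                "exactly one of 'params' or 'targets' must be supplied")
        if self.targets is not None and self.base is None:
            raise ValueError("'targets' requires a 'base' parameter set")
        return self


# ---------------------------------------------------------------------------
# doc <-> dataclass conversion

def _chamber(doc: ChamberDoc) -> ChamberParams:
    return ChamberParams(ees=doc.ees_mmhg_per_ml, v0=doc.v0_ml,
                         alpha=doc.alpha_per_ml, beta=doc.beta_mmhg,
                         tmax=doc.tmax_s, tau=doc.tau_s,
                         activation_delay=doc.activation_delay_s)


def _bed(doc: BedDoc) -> VascularBedParams:
    return VascularBedParams(rc=doc.rc_mmhg_s_per_ml, ra=doc.ra_mmhg_s_per_ml,
                             ca=doc.ca_ml_per_mmhg, cv=doc.cv_ml_per_mmhg,
                             rv=doc.rv_mmhg_s_per_ml)


def doc_to_params(doc: CirculationDoc) -> CirculationParams:
    return CirculationParams(
        lv=_chamber(doc.lv), rv=_chamber(doc.rv),
        la=_chamber(doc.la), ra=_chamber(doc.ra),
        systemic=_bed(doc.systemic), pulmonary=_bed(doc.pulmonary),
        hr=doc.hr_per_min,
        stressed_blood_volume=doc.stressed_blood_volume_ml,
        r_mitral=doc.valves.mitral_mmhg_s_per_ml,
        r_aortic=doc.valves.aortic_mmhg_s_per_ml,
        r_tricuspid=doc.valves.tricuspid_mmhg_s_per_ml,
        r_pulmonic=doc.valves.pulmonic_mmhg_s_per_ml,
    )


def params_to_doc(p: CirculationParams) -> CirculationDoc:
    def ch(c: ChamberParams) -> ChamberDoc:
        return ChamberDoc(ees_mmhg_per_ml=c.ees, v0_ml=c.v0,
                          alpha_per_ml=c.alpha, beta_mmhg=c.beta,
                          tmax_s=c.tmax, tau_s=c.tau,
                          activation_delay_s=c.activation_delay)

    def bed(b: VascularBedParams) -> BedDoc:
        return BedDoc(rc_mmhg_s_per_ml=b.rc, ra_mmhg_s_per_ml=b.ra,
                      ca_ml_per_mmhg=b.ca, cv_ml_per_mmhg=b.cv,
                      rv_mmhg_s_per_ml=b.rv)

    return CirculationDoc(
        hr_per_min=p.hr, stressed_blood_volume_ml=p.stressed_blood_volume,
        lv=ch(p.lv), rv=ch(p.rv), la=ch(p.la), ra=ch(p.ra),
        systemic=bed(p.systemic), pulmonary=bed(p.pulmonary),
        valves=ValvesDoc(mitral_mmhg_s_per_ml=p.r_mitral,
                         aortic_mmhg_s_per_ml=p.r_aortic,
                         tricuspid_mmhg_s_per_ml=p.r_tricuspid,
                         pulmonic_mmhg_s_per_ml=p.r_pulmonic))


def targets_from_doc(doc: TargetsDoc) -> FitTargets:
    return FitTargets(hr=doc.hr_per_min, lvef=doc.lvef_pct,
                      co=doc.co_l_per_min, cvp=doc.cvp_mmhg,
                      pcwp=doc.pcwp_mmhg, pasp=doc.pasp_mmhg,
                      padp=doc.padp_mmhg, mpap=doc.mpap_mmhg,
                      sbp=doc.sbp_mmhg, dbp=doc.dbp_mmhg, map=doc.map_mmhg)


def dcc_from_doc(doc: DccDoc, tmax: float | None = None) -> DccSettings:
    sys_dur = doc.systolic_duration_s
    if sys_dur is None:
        if tmax is None:
            raise ValueError("systolic_duration_s omitted and no tmax known")
        sys_dur = 1.5 * tmax - doc.trigger_delay_s - doc.rise_time_s \
            - doc.decline_time_s
    return DccSettings(amplitude=doc.amplitude_mmhg, offset=doc.offset_mmhg,
                       rise_time=doc.rise_time_s,
                       decline_time=doc.decline_time_s,
                       systolic_duration=sys_dur,
                       trigger_delay=doc.trigger_delay_s,
                       enabled=doc.enabled)


# ---------------------------------------------------------------------------
# fixtures and file IO

def _fixture_dir():
    return resources.files("dccsim.fixtures")


def list_fixtures() -> list[str]:
    """Names of the packaged fixture files (without extension)."""
    return sorted(p.name[:-5] for p in _fixture_dir().iterdir()
                  if p.name.endswith(".yaml"))


def fixture_path(name: str):
    p = _fixture_dir() / f"{name}.yaml"
    if not p.is_file():
        raise FileNotFoundError(
            f"no fixture {name!r}; available: {list_fixtures()}")
    return p


def _load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a scenario file; unknown keys are rejected."""
    return ScenarioConfig.model_validate(_load_yaml(path))


def load_targets(path_or_fixture) -> FitTargets:
    """Load a target profile from a file path or packaged fixture name."""
    p = Path(str(path_or_fixture))
    src = p if p.is_file() else fixture_path(str(path_or_fixture))
    data = _load_yaml(src)
    doc = TargetsDoc.model_validate(data.get("targets", data))
    return targets_from_doc(doc)


def load_cohort(path_or_fixture, n: int, seed: int = 0):
    """Build a :class:`~dccsim.stats.CohortSpec` from a targets fixture.

    The fixture must carry per-metric SDs next to its target means.
    """
    from .stats import CohortSpec

    p = Path(str(path_or_fixture))
    src = p if p.is_file() else fixture_path(str(path_or_fixture))
    data = _load_yaml(src)
    doc = TargetsDoc.model_validate(data.get("targets", data))
    if doc.sd is None:
        raise ValueError(f"{src}: fixture has no 'sd' block")
    sds = {_DOC_TO_METRIC[k]: float(v) for k, v in doc.sd.items()}
    return CohortSpec(means=targets_from_doc(doc), sds=sds, n=n, seed=seed)


def load_params(path_or_fixture) -> CirculationParams:
    """Load a circulation parameter set from a file or fixture name."""
    p = Path(str(path_or_fixture))
    src = p if p.is_file() else fixture_path(str(path_or_fixture))
    data = _load_yaml(src)
    doc = CirculationDoc.model_validate(data.get("params", data))
    return doc_to_params(doc)


def save_params(params: CirculationParams, path) -> None:
    doc = params_to_doc(params)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"schema_version": SCHEMA_VERSION,
                        "params": doc.model_dump()}, fh, sort_keys=False)


def _resolve_base(base, label: str) -> CirculationParams:
    if isinstance(base, CirculationDoc):
        return doc_to_params(base)
    if isinstance(base, str):
        if base == "ovine":
            from .presets import ovine_base
            return ovine_base()
        return load_params(base)
    raise ValueError(f"scenario {label!r}: cannot resolve base {base!r}")


def run_scenario(config: ScenarioConfig, outdir) -> dict:
    """Execute a scenario end to end and write its artifact bundle.

    Calibrates first when targets are given, integrates to steady
    state, summarizes, and extracts both PV loops.  Writes
    ``trace.csv``, ``summary.csv``, ``loops.csv``, the resolved
    parameter set and a run log into ``outdir``.  Returns a dict with
    the in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        fit = None
        if config.targets is not None:
            stage = "calibration"
            targets = targets_from_doc(config.targets)
            base = _resolve_base(config.base, config.label)
            base = base.with_hr(targets.hr)
            free = tuple(config.free_params or DEFAULT_FREE_PARAMS)
            fit = calibrate(targets, base, free, seed=config.seed,
                            dt=config.engine.dt_s)
            params = fit.params
        else:
            params = doc_to_params(config.params)

        stage = "assist setup"
        if config.assist is None:
            assist = None
        elif isinstance(config.assist, str):
            assist = preset(config.assist, tmax=params.lv.tmax)
        else:
            assist = dcc_from_doc(config.assist, tmax=params.lv.tmax)

        stage = "integration"
        trace = run_to_steady_state(
            params, assist=assist, dt=config.engine.dt_s,
            steady_tol=config.engine.steady_tol_ml,
            max_beats=config.engine.max_beats)
        stage = "summary"
        summary = summarize(trace)
        loops = {side: extract_loop(trace, side, getattr(params, side))
                 for side in ("lv", "rv")}
    except Exception as exc:
        raise RuntimeError(f"scenario {config.label!r} failed during "
                           f"{stage}: {exc}") from exc

    import pandas as pd

    trace.to_frame(config.decimate).to_csv(outdir / "trace.csv", index=False)
    pd.DataFrame([summary.as_dict()]).to_csv(outdir / "summary.csv",
                                             index=False)
    loop_rows = []
    for side, lp in loops.items():
        for v, p in zip(lp.volume, lp.pressure):
            loop_rows.append({"side": side, "volume_ml": v,
                              "pressure_mmhg": p})
    pd.DataFrame(loop_rows).to_csv(outdir / "loops.csv", index=False)
    save_params(params, outdir / "params.yaml")

    with open(outdir / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"label: {config.label}\nseed: {config.seed}\n"
                 f"dt_s: {config.engine.dt_s}\n"
                 f"steady_tol_ml: {config.engine.steady_tol_ml}\n"
                 f"beats_to_converge: {trace.beats_to_converge}\n")
        if fit is not None:
            fh.write(f"calibration_accepted: {fit.accepted}\n"
                     f"calibration_evals: {fit.iterations}\n")
            for name, rep in fit.report.items():
                fh.write(f"  {name}: target={rep['target']:.3f} "
                         f"achieved={rep['achieved']:.3f} "
                         f"error={rep['error']:+.3f} pass={rep['pass']}\n")
        fh.write("params: see params.yaml\n")
    return {"params": params, "trace": trace, "summary": summary,
            "loops": loops, "fit": fit}
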