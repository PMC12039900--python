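"""Validation-study arithmetic: effect sizes, cohort sampling, t-tests.

The device effect on hemodynamics is indexed as the per-sample absolute
change of each metric between the unassisted heart-failure state and
the same state with compression assist.  A seeded truncated-normal
sampler emulates a cohort of target profiles from published
mean +- SD summaries; metrics are drawn independently (no covariance is
published), with systolic >= mean >= diastolic ordering enforced by
redraw.  Student's t-tests are two-tailed at alpha = 0.05 with no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibrate import FitTargets
from .metrics import HemodynamicSummary

__all__ = ["EffectSummary", "CohortSpec", "delta", "sample_cohort",
           "ttest", "build_report", "EFFECT_METRICS", "REPORT_METRICS"]

#: Metrics differenced by :func:`delta` (order of the effect panel).
EFFECT_METRICS = ("sbp", "dbp", "map", "pasp", "padp", "mpap",
                  "cvp", "lvedp", "co", "lv_sv")

#: Row order of the summary report.
REPORT_METRICS = ("sbp", "dbp", "map", "pasp", "padp", "mpap",
                  "pcwp", "cvp", "lvedp", "lv_sv", "co")


@dataclass(frozen=True)
class EffectSummary:
    """Absolute change (assisted minus unassisted) of each metric."""

    sbp: float
    dbp: float
    map: float
    pasp: float
    padp: float
    mpap: float
    cvp: float
    lvedp: float
    co: float
    lv_sv: float
    sample_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in EFFECT_METRICS}


def delta(hf: HemodynamicSummary, assisted: HemodynamicSummary,
          sample_id: str = "") -> EffectSummary:
    """Elementwise change in the panel, assisted minus unassisted."""
    return EffectSummary(
        **{m: getattr(assisted, m) - getattr(hf, m) for m in EFFECT_METRICS},
        sample_id=sample_id,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Mean +- SD description of a cohort of target profiles."""

    means: FitTargets
    sds: dict[str, float]
    n: int
    seed: int = 0
    n_sigma: float = 3.0   # truncation half-width, in SDs

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("SDs must be non-negative")
        if self.n_sigma <= 0:
            raise ValueError("truncation width must be positive")


def _draw(rng: np.random.Generator, mean: float, sd: float, n_sigma: float,
          max_tries: int = 1000) -> float:
    if sd == 0:
        return mean
    lo, hi = mean - n_sigma * sd, mean + n_sigma * sd
    if lo >= hi:
        raise ValueError("infeasible truncation bounds")
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi and x > 0:
            return x
    raise ValueError("truncated draw failed; bounds exclude nearly all mass")


def sample_cohort(spec: CohortSpec) -> list[FitTargets]:
    """Seeded independent truncated-normal target profiles.

    Each metric is drawn around its cohort mean; the aortic and
    pulmonary triples are redrawn until systolic >= mean >= diastolic.
    Reproducible for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.means.metric_names()
    out: list[FitTargets] = []
    for _ in range(spec.n):
        for _try in range(1000):
            vals = {
                name: _draw(rng, getattr(spec.means, name),
                            spec.sds.get(name, 0.0), spec.n_sigma)
                for name in names
            }
            if (vals["sbp"] >= vals["map"] >= vals["dbp"]
                    and vals["pasp"] >= vals["mpap"] >= vals["padp"]):
                break
        else:
            raise ValueError("could not satisfy pressure ordering by redraw")
        out.append(FitTargets(**vals))
    return out


def ttest(a, b, paired: bool = False) -> tuple[float, float, bool]:
    """Classical two-sided Student's t-test.

    Pooled-variance (equal-variance) form for independent samples,
    difference-based for paired samples.  Returns ``(t, p, degenerate)``
    where ``degenerate`` flags a zero-variance input: zero variance with
    zero mean difference gives ``(0, 1)`` by convention; zero variance
    with a nonzero difference gives the limiting ``p = 0`` and is
    flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.isclose(d.mean(), 0.0):
                return 0.0, 1.0, True
            return float(np.sign(d.mean()) * np.inf), 0.0, True
        t, p = sps.ttest_rel(a, b)
        return float(t), float(p), False
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0, True
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, True
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), False


def _mean_sd_table(rows: dict[str, list[float]], metrics) -> pd.DataFrame:
    recs = []
    for label, values in rows.items():
        arr = np.asarray(values, dtype=float).reshape(len(values) // len(metrics),
                                                      len(metrics))
        for j, m in enumerate(metrics):
            col = arr[:, j]
            sd = float(col.std(ddof=1)) if col.size > 1 else 0.0
            recs.append({"label": label, "metric": m,
                         "mean": float(col.mean()), "sd": sd,
                         "formatted": f"{col.mean():.2f} ± {sd:.2f}"})
    return pd.DataFrame(recs)


def build_report(
    states: list[tuple[str, HemodynamicSummary]],
    effects: list[EffectSummary] | None = None,
) -> dict[str, pd.DataFrame]:
    """Mean +- SD tables over labeled states and effect panels.

    ``states`` pairs a condition label (e.g. "baseline", "hf",
    "hf+dcc") with a summary; labels may repeat.  Returns a dict with a
    per-label ``summary`` table (one row per metric in the standard
    panel order) and, when effects are given, an ``effects`` table.
    """
    if not states:
        raise ValueError("at least one labeled state is required")
    rows: dict[str, list[float]] = {}
    for label, summ in states:
        rows.setdefault(label, []).extend(
            getattr(summ, m) for m in REPORT_METRICS)
    out = {"summary": _mean_sd_table(rows, REPORT_METRICS)}
    if effects:
        erow = {"effect": [v for e in effects
                           for v in (getattr(e, m) for m in EFFECT_METRICS)]}
        out["effects"] = _mean_sd_table(erow, EFFECT_METRICS)
    return out


def render_report(tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable rendering of :func:`build_report` output."""
    parts = []
    for name, df in tables.items():
        parts.append(f"== {name} ==")
        pivot = df.pivot_table(index="metric", columns="label",
                               values="formatted", aggfunc="first",
                               sort=False)
        parts.append(pivot.to_string())
    return "\n\n".join(parts)
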