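"""Effect sizes, cohort sampling and the t-test battery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dccsim.stats import (
    EFFECT_METRICS,
    REPORT_METRICS,
    CohortSpec,
    build_report,
    delta,
    render_report,
    sample_cohort,
    ttest,
)


class TestDelta:
    def test_self_difference_is_zero(self, validation):
        d = delta(validation.hf, validation.hf)
        assert all(v == 0.0 for v in d.as_dict().values())

    def test_elementwise_subtraction(self, validation):
        d = delta(validation.hf, validation.hf_dcc19)
        assert d.map == pytest.approx(
            validation.hf_dcc19.map - validation.hf.map)
        assert d.co == pytest.approx(
            validation.hf_dcc19.co - validation.hf.co)


class TestCohortSampling:
    def test_zero_sd_returns_means(self, hf_targets):
        spec = CohortSpec(means=hf_targets,
                          sds={m: 0.0 for m in hf_targets.metric_names()},
                          n=3, seed=5)
        for sample in sample_cohort(spec):
            for m in hf_targets.metric_names():
                assert getattr(sample, m) == getattr(hf_targets, m)

    def test_seeded_determinism(self, hf_targets):
        spec = CohortSpec(means=hf_targets, sds={"co": 0.22, "sbp": 3.0},
                          n=6, seed=11)
        a = sample_cohort(spec)
        b = sample_cohort(spec)
        for x, y in zip(a, b):
            assert x == y

    def test_monte_carlo_moments(self, hf_targets):
        spec = CohortSpec(means=hf_targets, sds={"co": 0.22}, n=10_000,
                          seed=3)
        draws = np.array([s.co for s in sample_cohort(spec)])
        se = 0.22 / math.sqrt(len(draws))
        assert abs(draws.mean() - 1.91) < 3 * se

    def test_pressure_ordering_enforced(self, hf_targets):
        sds = {"sbp": 6.0, "dbp": 6.0, "map": 6.0,
               "pasp": 4.0, "padp": 4.0, "mpap": 4.0}
        spec = CohortSpec(means=hf_targets, sds=sds, n=200, seed=9)
        for s in sample_cohort(spec):
            assert s.sbp >= s.map >= s.dbp
            assert s.pasp >= s.mpap >= s.padp

    def test_invalid_specs_rejected(self, hf_targets):
        with pytest.raises(ValueError):
            CohortSpec(means=hf_targets, sds={}, n=1)
        with pytest.raises(ValueError):
            CohortSpec(means=hf_targets, sds={"co": -1.0}, n=3)


def pooled_t_oracle(a, b):
    """Independent two-sample pooled-variance t, written out longhand."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


class TestTtest:
    def test_identical_paired_samples(self):
        t, p, degenerate = ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                 paired=True)
        assert (t, p) == (0.0, 1.0)
        assert degenerate

    def test_constant_shift_zero_variance_flagged(self):
        t, p, degenerate = ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0],
                                 paired=True)
        assert degenerate
        assert p == 0.0
        assert math.isinf(t) and t < 0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_matches_longhand_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=rng.integers(3, 20))
        b = rng.normal(0.3, 1.2, size=rng.integers(3, 20))
        t, p, degenerate = ttest(a, b)
        assert not degenerate
        assert t == pytest.approx(pooled_t_oracle(a, b), abs=1e-6)
        assert 0.0 <= p <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.booleans())
    def test_antisymmetric_in_sample_order(self, seed, paired):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        a = rng.normal(0.0, 1.0, size=n)
        b = rng.normal(0.5, 1.0, size=n)
        t1, p1, _ = ttest(a, b, paired=paired)
        t2, p2, _ = ttest(b, a, paired=paired)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ttest([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


class TestReport:
    def test_single_state_has_zero_sd(self, validation):
        tables = build_report([("hf", validation.hf)])
        assert (tables["summary"]["sd"] == 0.0).all()
        assert len(tables["summary"]) == len(REPORT_METRICS)

    def test_effect_table_and_linearity(self, validation):
        effects = [delta(validation.hf, validation.hf_dcc19, "a"),
                   delta(validation.hf, validation.hf_dcc30, "b")]
        tables = build_report(
            [("hf", validation.hf), ("hf", validation.hf)], effects)
        eff = tables["effects"]
        assert len(eff) == len(EFFECT_METRICS)
        mean_dmap = eff.loc[eff.metric == "map", "mean"].item()
        assert mean_dmap == pytest.approx(
            (effects[0].map + effects[1].map) / 2)

    def test_formatting_two_decimals(self, validation):
        tables = build_report([("hf", validation.hf)])
        cell = tables["summary"].loc[
            tables["summary"].metric == "co", "formatted"].item()
        assert cell == f"{validation.hf.co:.2f} ± 0.00"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_report([])

    def test_rendering_mentions_every_metric(self, validation):
        text = render_report(build_report([("hf", validation.hf)]))
        for m in REPORT_METRICS:
            assert m in text
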