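"""Trapezoidal assist waveform and its coupling to the ventricles."""

import numpy as np
import pytest

from dccsim.dcc import DccSettings, apply_assist, dcc_pressure, preset

CYCLE = 0.66


def settings(**kw) -> DccSettings:
    base = dict(amplitude=34.0, offset=4.0, rise_time=0.10,
                decline_time=0.05, systolic_duration=0.20,
                trigger_delay=0.0)
    base.update(kw)
    return DccSettings(**base)


class TestWaveform:
    def test_plateau_is_amplitude_minus_offset(self):
        # 34 mm Hg amplitude over a 4 mm Hg deflate offset -> +30 plateau
        s = settings()
        assert dcc_pressure(0.15, s, CYCLE) == pytest.approx(30.0)

    def test_disabled_contributes_nothing(self):
        s = settings(enabled=False)
        for t in np.linspace(0.0, CYCLE, 7, endpoint=False):
            assert dcc_pressure(t, s, CYCLE) == 0.0

    def test_rise_midpoint_linear_interpolation(self):
        s = settings()
        assert dcc_pressure(0.05, s, CYCLE) == pytest.approx(-4.0 + 34.0 / 2)

    def test_diastolic_level_is_negative_offset(self):
        s = settings()
        assert dcc_pressure(0.5, s, CYCLE) == pytest.approx(-4.0)

    def test_decline_returns_to_offset(self):
        s = settings()
        end = s.rise_time + s.systolic_duration + s.decline_time
        assert dcc_pressure(end - 1e-9, s, CYCLE) == pytest.approx(-4.0,
                                                                  abs=1e-5)

    def test_periodic_via_trigger_delay(self):
        # plateau spans [0.6, 0.8) against a 0.66 s cycle, so it wraps
        # into the start of the next cycle
        s = settings(trigger_delay=0.5)
        assert dcc_pressure(0.5 + 0.15, s, CYCLE) == pytest.approx(30.0)
        assert dcc_pressure(0.05, s, CYCLE) == pytest.approx(30.0)

    def test_oversized_trapezoid_rejected(self):
        s = settings(systolic_duration=0.6)
        with pytest.raises(ValueError):
            dcc_pressure(0.1, s, CYCLE)

    def test_time_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            dcc_pressure(CYCLE, settings(), CYCLE)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            settings(amplitude=-1.0)
        with pytest.raises(ValueError):
            settings(rise_time=-0.1)


class TestApplyAssist:
    @pytest.mark.parametrize("p_lv,p_rv,p_dcc,expected", [
        (50.0, 20.0, 19.0, (69.0, 39.0)),
        (50.0, 20.0, 0.0, (50.0, 20.0)),
        (50.0, 20.0, -4.0, (46.0, 16.0)),
    ])
    def test_uniform_biventricular_addition(self, p_lv, p_rv, p_dcc,
                                            expected):
        assert apply_assist(p_lv, p_rv, p_dcc) == pytest.approx(expected)


class TestPresets:
    def test_plateau_levels(self):
        assert preset("dcc19").plateau == pytest.approx(19.0)
        assert preset("dcc30").plateau == pytest.approx(30.0)
        assert preset("dcc30").amplitude == pytest.approx(34.0)
        assert preset("dcc30").offset == pytest.approx(4.0)

    def test_plateau_duration_tracks_tmax(self):
        s = preset("dcc19", tmax=0.25)
        end = s.trigger_delay + s.rise_time + s.systolic_duration \
            + s.decline_time
        assert end == pytest.approx(1.5 * 0.25)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("dcc99")

    def test_too_short_tmax_rejected(self):
        with pytest.raises(ValueError):
            preset("dcc19", tmax=0.05)


class TestAssistOffIdentity:
    def test_disabled_assist_is_bit_identical_to_no_assist(self, base_params):
        from dccsim.engine import run_to_steady_state

        off = DccSettings(amplitude=23.0, enabled=False)
        a = run_to_steady_state(base_params)
        b = run_to_steady_state(base_params, assist=off)
        assert np.array_equal(a.volumes, b.volumes)
        for k in a.pressures:
            assert np.array_equal(a.pressures[k], b.pressures[k])

    def test_atria_receive_no_assist_term(self, validation, hf_trace):
        from dccsim.dcc import preset as mk_preset
        from dccsim.experiments import assisted_steady_state

        params = validation.hf_fit.params
        a19 = mk_preset("dcc19", tmax=params.lv.tmax)
        tr = assisted_steady_state(params, a19, hf_trace)
        # reconstruct atrial pressures from volumes and the passive/active
        # relations: they must match the stored traces exactly (no added
        # term), unlike the ventricles during the plateau
        from dccsim.engine import _activation_curve
        for name, ch in (("la", params.la), ("ra", params.ra)):
            e = _activation_curve(tr.t, ch, params.cycle_length)
            dv = tr.volume(name) - ch.v0
            expect = e * ch.ees * dv + (1 - e) * ch.beta * np.expm1(
                ch.alpha * dv)
            assert np.allclose(tr.pressures[name], expect, atol=1e-9)
        assert np.max(np.abs(
            tr.pressures["lv"] - (tr.pressures["lv"] - tr.p_dcc))) > 0
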