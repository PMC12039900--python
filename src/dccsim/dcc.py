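"""Direct cardiac compression (DCC) assist waveform.

The device applies cyclic positive and negative pressure to the
epicardial surface of both ventricles in synchrony with the beat.  In
the model this is a trapezoidal pressure waveform added identically to
the LV and RV pressures: a linear rise to a constant systolic plateau,
a linear decline, and a constant negative deflate pressure held for the
remainder of diastole.  The plateau sits at ``amplitude - offset`` above
zero and diastole sits at ``-offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["DccSettings", "dcc_pressure", "apply_assist", "preset"]


@dataclass(frozen=True)
class DccSettings:
    """Trapezoidal assist-waveform parameters.

    Parameters
    ----------
    amplitude : float
        Total pressure excursion from the diastolic level to the
        systolic plateau, mm Hg.
    offset : float
        Magnitude of the negative diastolic (deflate) pressure, mm Hg;
        the waveform sits at ``-offset`` throughout diastole.
    rise_time : float
        Inflation ramp duration ("Rise"), s.
    decline_time : float
        Deflation ramp duration ("Decline"), s.
    systolic_duration : float
        Plateau hold time, s.
    trigger_delay : float
        Inflation start relative to ventricular activation onset, s.
    enabled : bool
        Disabled settings contribute exactly zero pressure.
    """

    amplitude: float
    offset: float = 4.0
    rise_time: float = 0.10
    decline_time: float = 0.05
    systolic_duration: float = 0.20
    trigger_delay: float = 0.02
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.offset < 0:
            raise ValueError("amplitude and offset must be non-negative")
        if self.rise_time < 0 or self.decline_time < 0:
            raise ValueError("rise_time and decline_time must be non-negative")
        if self.systolic_duration < 0 or self.trigger_delay < 0:
            raise ValueError("systolic_duration and trigger_delay must be non-negative")

    @property
    def plateau(self) -> float:
        """Systolic plateau pressure above zero, mm Hg."""
        return self.amplitude - self.offset

    @property
    def duration(self) -> float:
        """Total active (rise + plateau + decline) duration, s."""
        return self.rise_time + self.systolic_duration + self.decline_time


#: Named device settings.  The 30 mm Hg plateau level uses an amplitude
#: of 34 mm Hg over a 4 mm Hg diastolic offset; the 19 mm Hg level keeps
#: the same diastolic offset.
_PRESET_LEVELS = {"dcc19": 23.0, "dcc30": 34.0}


def preset(name: str, tmax: float | None = None, trigger_delay: float = 0.02,
           rise_time: float = 0.10, decline_time: float = 0.05) -> DccSettings:
    """Build a named device preset ("dcc19" or "dcc30").

    When the ventricular ``tmax`` is given, the plateau duration is
    chosen so that the decline completes at 1.5*tmax (end of the
    systolic phase of the activation function).
    """
    try:
        amplitude = _PRESET_LEVELS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown DCC preset {name!r}; available: {sorted(_PRESET_LEVELS)}"
        ) from None
    settings = DccSettings(amplitude=amplitude, offset=4.0, rise_time=rise_time,
                           decline_time=decline_time, trigger_delay=trigger_delay)
    if tmax is not None:
        sys_dur = 1.5 * tmax - trigger_delay - rise_time - decline_time
        if sys_dur <= 0:
            raise ValueError("tmax too short for the preset ramp times")
        settings = replace(settings, systolic_duration=sys_dur)
    return settings


def dcc_pressure(
    t_in_cycle: float,
    settings: DccSettings,
    cycle_length: float,
    onset: float = 0.0,
) -> float:
    """Assist pressure at a time within the cycle, mm Hg.

    Piecewise-linear trapezoid synchronized to ventricular activation
    onset: ``-offset`` before the trigger, linear rise over
    ``rise_time`` to the plateau ``amplitude - offset``, constant for
    ``systolic_duration``, linear decline back to ``-offset``, then
    constant for the rest of the cycle.  Periodic.

    Raises
    ------
    ValueError
        If the active portion of the trapezoid does not fit in one
        cycle, or ``t_in_cycle`` is outside ``[0, cycle_length)``.
    """
    if not settings.enabled:
        return 0.0
    if settings.duration >= cycle_length:
        raise ValueError("trapezoid (rise + plateau + decline) exceeds the cycle")
    if not 0.0 <= t_in_cycle < cycle_length:
        raise ValueError("t_in_cycle must lie in [0, cycle_length)")
    tp = (t_in_cycle - onset - settings.trigger_delay) % cycle_length
    lo = -settings.offset
    hi = settings.plateau
    if tp < settings.rise_time:
        return lo + (hi - lo) * tp / settings.rise_time
    tp -= settings.rise_time
    if tp < settings.systolic_duration:
        return hi
    tp -= settings.systolic_duration
    if tp < settings.decline_time:
        return hi - (hi - lo) * tp / settings.decline_time
    return lo


def apply_assist(p_lv: float, p_rv: float, p_dcc: float) -> tuple[float, float]:
    """Add the epicardial compression pressure to both ventricles.

    The same additive term acts on LV and RV (uniform biventricular
    assist); atrial pressures receive no direct term.
    """
    return p_lv + p_dcc, p_rv + p_dcc
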