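"""Compiled fixed-step integrator for the closed loop.

The model parameters are packed into a flat float64 vector so the whole
beat loop can run under numba.  Layout (indices):

  0-6    LV chamber:  ees, v0, alpha, beta, tmax, tau, activation_delay
  7-13   RV chamber
  14-20  LA chamber
  21-27  RA chamber
  28-32  systemic bed:  rc, ra, ca, cv, rv
  33-37  pulmonary bed
  38     cycle length T, s
  39-42  valve resistances: mitral, aortic, tricuspid, pulmonic
  43     assist enabled (0/1)
  44-48  assist: amplitude, offset, rise, plateau duration, decline
  49     assist trigger time within the cycle (absolute), s

State order matches :data:`dccsim.model.COMPARTMENTS`:
LV, RV, LA, RA, systemic arterial, systemic venous, pulmonary arterial,
pulmonary venous.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NPARAM = 50

# offsets
LV, RV, LA, RA = 0, 7, 14, 21
SYS, PUL = 28, 33
I_T = 38
I_VALVES = 39
I_DCC = 43


@njit(cache=True, fastmath=False)
def _act(phi, tmax, tau, delay, T):
    tp = (phi - delay) % T
    ts = 1.5 * tmax
    if tp <= ts:
        return 0.5 * (np.sin(np.pi * tp / tmax - np.pi / 2.0) + 1.0)
    return 0.5 * np.exp(-(tp - ts) / tau)


@njit(cache=True, fastmath=False)
def _chamber(vol, phi, mp, o, T):
    e = _act(phi, mp[o + 4], mp[o + 5], mp[o + 6], T)
    dv = vol - mp[o + 1]
    return e * mp[o] * dv + (1.0 - e) * mp[o + 3] * np.expm1(mp[o + 2] * dv)


@njit(cache=True, fastmath=False)
def _dcc(phi, mp, T):
    if mp[I_DCC] == 0.0:
        return 0.0
    amp = mp[44]
    off = mp[45]
    tp = (phi - mp[49]) % T
    lo = -off
    hi = amp - off
    rise = mp[46]
    if tp < rise:
        return lo + (hi - lo) * tp / rise
    tp -= rise
    if tp < mp[47]:
        return hi
    tp -= mp[47]
    dec = mp[48]
    if tp < dec:
        return hi - (hi - lo) * tp / dec
    return lo


@njit(cache=True, fastmath=False)
def _deriv(phi, v, mp, dv):
    T = mp[I_T]
    pdcc = _dcc(phi, mp, T)
    plv = _chamber(v[0], phi, mp, LV, T) + pdcc
    prv = _chamber(v[1], phi, mp, RV, T) + pdcc
    pla = _chamber(v[2], phi, mp, LA, T)
    pra = _chamber(v[3], phi, mp, RA, T)
    psa = v[4] / mp[SYS + 2]
    psv = v[5] / mp[SYS + 3]
    ppa = v[6] / mp[PUL + 2]
    ppv = v[7] / mp[PUL + 3]

    q_mv = max(0.0, pla - plv) / mp[I_VALVES + 0]
    q_av = max(0.0, plv - psa) / (mp[I_VALVES + 1] + mp[SYS + 0])
    q_sys = (psa - psv) / mp[SYS + 1]
    q_ven = (psv - pra) / mp[SYS + 4]
    q_tv = max(0.0, pra - prv) / mp[I_VALVES + 2]
    q_pv = max(0.0, prv - ppa) / (mp[I_VALVES + 3] + mp[PUL + 0])
    q_pul = (ppa - ppv) / mp[PUL + 1]
    q_pvr = (ppv - pla) / mp[PUL + 4]

    dv[0] = q_mv - q_av
    dv[1] = q_tv - q_pv
    dv[2] = q_pvr - q_mv
    dv[3] = q_ven - q_tv
    dv[4] = q_av - q_sys
    dv[5] = q_sys - q_ven
    dv[6] = q_pv - q_pul
    dv[7] = q_pul - q_pvr


@njit(cache=True, fastmath=False)
def _rk4_beat(v, mp, nsteps, out):
    """Integrate one beat in place; ``out`` of shape (0 or nsteps+1, 8).

    Returns the index of a compartment that went negative/NaN, or -1.
    """
    T = mp[I_T]
    dt = T / nsteps
    record = out.shape[0] == nsteps + 1
    if record:
        out[0] = v
    k1 = np.empty(8)
    k2 = np.empty(8)
    k3 = np.empty(8)
    k4 = np.empty(8)
    tmp = np.empty(8)
    for i in range(nsteps):
        phi = i * dt
        _deriv(phi, v, mp, k1)
        for j in range(8):
            tmp[j] = v[j] + 0.5 * dt * k1[j]
        _deriv(phi + 0.5 * dt, tmp, mp, k2)
        for j in range(8):
            tmp[j] = v[j] + 0.5 * dt * k2[j]
        _deriv(phi + 0.5 * dt, tmp, mp, k3)
        for j in range(8):
            tmp[j] = v[j] + dt * k3[j]
        _deriv(phi + dt, tmp, mp, k4)
        for j in range(8):
            v[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if not np.isfinite(v[j]) or v[j] < 0.0:
                return j
        if record:
            out[i + 1] = v
    return -1


@njit(cache=True, fastmath=False)
def integrate_to_steady(v0, mp, nsteps, max_beats, tol):
    """Beat-by-beat integration until start-of-beat volumes settle.

    Returns (volumes at start of the converged beat, beats used,
    worst compartment index, status) with status 0 = converged,
    1 = beat cap reached, 2 = negative/non-finite volume.
    """
    v = v0.copy()
    prev = v.copy()
    none = np.empty((0, 8))
    worst = 0
    for beat in range(max_beats):
        bad = _rk4_beat(v, mp, nsteps, none)
        if bad >= 0:
            return v, beat + 1, bad, 2
        d = -1.0
        for j in range(8):
            dj = abs(v[j] - prev[j])
            if dj > d:
                d = dj
                worst = j
        if d < tol:
            return v, beat + 1, worst, 0
        prev[:] = v
    return v, max_beats, worst, 1


@njit(cache=True, fastmath=False)
def record_beat(vstart, mp, nsteps):
    """Integrate one beat from ``vstart`` recording every step."""
    out = np.empty((nsteps + 1, 8))
    v = vstart.copy()
    bad = _rk4_beat(v, mp, nsteps, out)
    return out, bad
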