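"""Reference parameter sets.

:func:`ovine_base` builds the starting parameter set used for fitting
an adult-sheep circulation.  Chamber timing scales with the cycle: the
atria activate at the start of the cycle and finish their systole at
ventricular activation onset (a PR-like interval of 0.16 of the cycle);
ventricular Tmax and tau start at typical values and are normally freed
during calibration.  EDPVR stiffness, venous compliances and return
resistances are fixed properties of the base set: passive chamber
compliance does not change acutely, so the fitting protocol leaves them
alone.
"""

from __future__ import annotations

from .model import ChamberParams, CirculationParams, VascularBedParams

__all__ = ["ovine_base"]


def ovine_base(hr: float = 91.0) -> CirculationParams:
    """Base circulation for an adult sheep at the given heart rate.

    The EDPVR constants place the left ventricle near 15 mm Hg at an
    end-diastolic volume of ~72 mL (passive stiffness ~0.9 mm Hg/mL
    there) and the right ventricle near 13.5 mm Hg at ~47 mL; both are
    held fixed across disease states, since passive chamber compliance
    does not change acutely.  Elastances, afterloads and stressed volume
    are starting values that calibration normally overrides.
    """
    T = 60.0 / hr
    pr = 0.16 * T                 # atrial systole ends at ventricular onset
    atrial_tmax = pr / 1.5
    lv = ChamberParams(ees=1.0, v0=5.56, alpha=0.0588, beta=0.30,
                       tmax=0.26, tau=0.045, activation_delay=pr)
    rv = ChamberParams(ees=1.5, v0=19.0, alpha=0.0495, beta=4.50,
                       tmax=0.26, tau=0.045, activation_delay=pr)
    la = ChamberParams(ees=0.35, v0=3.0, alpha=0.06, beta=0.45,
                       tmax=atrial_tmax, tau=0.035, activation_delay=0.0)
    ra = ChamberParams(ees=0.15, v0=3.0, alpha=0.06, beta=0.40,
                       tmax=atrial_tmax, tau=0.035, activation_delay=0.0)
    systemic = VascularBedParams(rc=0.038, ra=0.72, ca=1.3, cv=40.0, rv=0.055)
    pulmonary = VascularBedParams(rc=0.008, ra=0.035, ca=2.6, cv=9.0, rv=0.012)
    return CirculationParams(lv=lv, rv=rv, la=la, ra=ra, systemic=systemic,
                             pulmonary=pulmonary, hr=hr,
                             stressed_blood_volume=1100.0)
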