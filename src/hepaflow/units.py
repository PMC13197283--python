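"""Unit conversions between internal SI and clinical reporting units.

Everything inside the solver is SI (m, Pa, m^3/s, Pa.s).  Clinical units
(mm, mmHg, ml/min, ml/(min.mmHg)) appear only at configuration and
reporting boundaries.
"""

MMHG_TO_PA = 133.322
"""One millimetre of mercury in pascal."""

ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0
"""One millilitre per minute in cubic metres per second."""

CONDUCTANCE_CLINICAL_TO_SI = ML_PER_MIN_TO_M3_PER_S / MMHG_TO_PA
"""One ml/(min.mmHg) in m^3/(s.Pa)."""

MM_TO_M = 1e-3
UM_TO_M = 1e-6


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p / MMHG_TO_PA


def mlmin_to_si(q):
    return q * ML_PER_MIN_TO_M3_PER_S


def si_to_mlmin(q):
    return q / ML_PER_MIN_TO_M3_PER_S


def conductance_to_si(c):
    """ml/(min.mmHg) -> m^3/(s.Pa)."""
    return c * CONDUCTANCE_CLINICAL_TO_SI


def conductance_to_clinical(c):
    """m^3/(s.Pa) -> ml/(min.mmHg)."""
    return c / CONDUCTANCE_CLINICAL_TO_SI
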