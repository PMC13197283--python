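"""Diameter- and hematocrit-dependent apparent blood viscosity.

In microvessels the red-cell scale is comparable to the vessel diameter, so
bulk rheology does not apply (the Fåhræus–Lindqvist effect).  This module
implements the Pries in-vitro correlation for the relative apparent
viscosity of blood as a function of tube diameter ``D`` (micrometres) and
discharge hematocrit ``Hct_D``::

    eta_rel(D, Hct) = 1 + (eta_45(D) - 1) * ((1 - Hct)^C - 1) / ((1 - 0.45)^C - 1)
    eta_45(D)       = 220 e^{-1.3 D} - 2.44 e^{-0.06 D^0.645} + 3.2
    C(D)            = (0.8 + e^{-0.075 D}) (-1 + S) + S,   S = 1 / (1 + 1e-11 D^12)

The apparent (dimensional) viscosity is ``mu_ap = eta_rel * mu_SM`` where
``mu_SM`` is the suspending-medium (plasma) viscosity.  The correlation's
constants are dimensionally meaningful only with ``D`` in micrometres; all
public functions here take micrometres and return Pa.s for dimensional
quantities.

Lumped sinusoid channels use a single fixed effective viscosity: the
arithmetic mean of the apparent viscosities at the two endpoints of the
physiological sinusoid diameter range (7 and 15 um by default), which
evaluates to about 0.0018 Pa.s at Hct 0.45.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MU_SM",
    "REFERENCE_HEMATOCRIT",
    "ViscosityModel",
    "viscosity_curvature",
    "relative_viscosity_045",
    "relative_viscosity",
    "apparent_viscosity",
    "sinusoid_effective_viscosity",
    "asymptotic_viscosity",
]

MU_SM = 0.00134
"""Suspending-medium (plasma) viscosity, Pa.s."""

REFERENCE_HEMATOCRIT = 0.45

_ASYMPTOTIC_DIAMETER_UM = 1e4
"""Diameter at which the correlation is within float precision of its large-D limit."""


def viscosity_curvature(diameter_um):
    """Curvature exponent C of the viscosity-hematocrit relationship."""
    d = np.asarray(diameter_um, dtype=float)
    shape = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + np.exp(-0.075 * d)) * (shape - 1.0) + shape


def relative_viscosity_045(diameter_um):
    """Relative apparent viscosity at the reference hematocrit of 0.45."""
    d = np.asarray(diameter_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("tube diameter must be positive")
    return 220.0 * np.exp(-1.3 * d) - 2.44 * np.exp(-0.06 * d**0.645) + 3.2


def relative_viscosity(diameter_um, hematocrit=REFERENCE_HEMATOCRIT):
    """Relative apparent viscosity of blood in a tube of given diameter.

    Parameters
    ----------
    diameter_um : array_like
        Tube diameter in micrometres, > 0.
    hematocrit : float
        Discharge hematocrit in [0, 1).

    Returns
    -------
    ndarray or float
        Dimensionless relative viscosity; >= 1 for positive hematocrit and
        exactly 1 at zero hematocrit.
    """
    hct = float(hematocrit)
    if not 0.0 <= hct < 1.0:
        raise ValueError(f"hematocrit must be in [0, 1), got {hct}")
    eta45 = relative_viscosity_045(diameter_um)
    c = viscosity_curvature(diameter_um)
    num = (1.0 - hct) ** c - 1.0
    den = (1.0 - REFERENCE_HEMATOCRIT) ** c - 1.0
    return 1.0 + (eta45 - 1.0) * num / den


def apparent_viscosity(diameter_um, hematocrit=REFERENCE_HEMATOCRIT, mu_sm=MU_SM):
    """Apparent viscosity mu_ap = eta_rel * mu_SM, in Pa.s."""
    if mu_sm <= 0:
        raise ValueError("suspending-medium viscosity must be positive")
    return relative_viscosity(diameter_um, hematocrit) * mu_sm


def asymptotic_viscosity(hematocrit=REFERENCE_HEMATOCRIT, mu_sm=MU_SM):
    """Large-diameter limit of the apparent viscosity (macro-vessel value)."""
    return apparent_viscosity(_ASYMPTOTIC_DIAMETER_UM, hematocrit, mu_sm)


@dataclass(frozen=True)
class ViscosityModel:
    """Rheology parameters shared by a whole-network simulation.

    Attributes
    ----------
    mu_sm : float
        Suspending-medium viscosity, Pa.s.
    hematocrit : float
        Discharge hematocrit (fraction of red-cell volume).
    sinusoid_range_um : tuple of float
        (low, high) endpoints of the sinusoid diameter range in micrometres;
        the fixed sinusoid effective viscosity is the mean of the apparent
        viscosities at these two diameters.
    """

    mu_sm: float = MU_SM
    hematocrit: float = REFERENCE_HEMATOCRIT
    sinusoid_range_um: tuple = (7.0, 15.0)

    def __post_init__(self):
        if self.mu_sm <= 0:
            raise ValueError("mu_sm must be positive")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")
        lo, hi = self.sinusoid_range_um
        if lo <= 0 or hi < lo:
            raise ValueError("sinusoid diameter range must be positive and ordered")

    def edge_viscosity(self, diameter_um):
        return apparent_viscosity(diameter_um, self.hematocrit, self.mu_sm)

    def sinusoid_viscosity(self):
        return sinusoid_effective_viscosity(self)

    def collateral_viscosity(self):
        """Macro-vessel (large-diameter asymptotic) apparent viscosity."""
        return asymptotic_viscosity(self.hematocrit, self.mu_sm)


def sinusoid_effective_viscosity(model: ViscosityModel | None = None):
    """Fixed effective viscosity of the lumped sinusoid channels, Pa.s.

    Arithmetic mean of the apparent viscosities at the endpoints of the
    sinusoid diameter range; about 0.0018 Pa.s with the defaults.
    """
    if model is None:
        model = ViscosityModel()
    lo, hi = model.sinusoid_range_um
    mus = apparent_viscosity(np.array([lo, hi]), model.hematocrit, model.mu_sm)
    return float(mus.mean())
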