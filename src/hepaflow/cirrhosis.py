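"""Disease-stage parameterization of the liver model.

Cirrhosis is represented by three coordinated alterations:

* per-Couinaud-segment heterogeneity of the lumped sinusoid conductances —
  each channel's conductance is an i.i.d. draw from a segment-specific
  log-normal (or Gaussian) distribution whose arithmetic mean and standard
  deviation, normalized by the healthy reference c0_sin, encode right-lobe
  atrophy (low mean, high spread) versus left-lobe preservation;
* portal-vein dilatation (base lumen radius 4.9 / 6.4 / 7.2 mm for
  healthy / early / advanced) and redistributed segment volumes;
* a portosystemic collateral: a single edge from the PV inlet to the vena
  cava whose conductance is expressed as a fraction of the healthy
  whole-liver normalization constant c_liver = 176 ml/(min.mmHg).

The healthy stage uses a pressure boundary condition at the PV inlet
(5 mmHg); both cirrhotic stages prescribe the clinically measured portal
inflow of 820 ml/min instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .hemodynamics import BoundaryConditionSet
from .vasculature import (
    CLASS_CODE,
    SEGMENTS,
    SegmentVolumeTable,
    NetworkTopology,
    VascularSpecError,
)

__all__ = [
    "C_SIN0_CLINICAL",
    "C_SIN_FLOOR_CLINICAL",
    "C_LIVER_CLINICAL",
    "COLLATERAL_SWEEP_CLINICAL",
    "STAGES",
    "SinusoidDistributionSpec",
    "StageParameters",
    "CollateralSpec",
    "sample_sinusoid_conductances",
    "stage_parameters",
    "attach_collateral",
    "conductance_diameter_sensitivity",
]

C_SIN0_CLINICAL = 1.2e-5
"""Healthy lumped sinusoid conductance, ml/(min.mmHg) (calibrated reference)."""

C_SIN_FLOOR_CLINICAL = 1.2e-6
"""Lower limit on the configured mean sinusoid conductance, ml/(min.mmHg)."""

C_LIVER_CLINICAL = 176.0
"""Whole-liver conductance normalization constant for c_col, ml/(min.mmHg)."""

COLLATERAL_SWEEP_CLINICAL = (1.76, 5.57, 17.6, 55.7, 176.0)
"""Swept collateral conductances, log-spaced, ml/(min.mmHg)."""

STAGES = ("healthy", "early", "advanced")

# (mean fraction, sd fraction) of c0_sin per segment group and stage; the
# early-stage mean for segments 2/3 is not fixed by the reference data and
# is configurable (0.8 default).
_TABLE_GROUPS = (("6", "7"), ("5", "8"), ("1", "4a", "4b"), ("2", "3"))
_STAGE_FIELDS = {
    "early": {
        ("6", "7"): (0.18, 0.12),
        ("5", "8"): (0.32, 0.08),
        ("1", "4a", "4b"): (0.51, 0.055),
        ("2", "3"): (None, 0.035),  # mean filled from early_seg23_mean_fraction
    },
    "advanced": {
        ("6", "7"): (0.10, 0.16),
        ("5", "8"): (0.16, 0.13),
        ("1", "4a", "4b"): (0.25, 0.10),
        ("2", "3"): (0.40, 0.08),
    },
}

_SEGMENT_GROUP_VOLUMES = {
    # (segment I, segments II-III, segments IV-VIII) totals in cm^3
    "healthy": (28.0, 242.0, 1248.0),
    "early": (28.0, 242.0, 1248.0),
    "advanced": (77.0, 341.0, 1035.0),
}

_PV_BASE_RADIUS_MM = {"healthy": 4.9, "early": 6.4, "advanced": 7.2}

DEFAULT_EARLY_SEG23_MEAN_FRACTION = 0.8


@dataclass(frozen=True)
class SinusoidDistributionSpec:
    """Per-segment distribution of lumped sinusoid conductances.

    ``mean_fraction`` and ``sd_fraction`` map each segment label to the
    arithmetic mean and standard deviation of its conductance
    distribution, normalized by the healthy reference ``c0``.
    """

    family: str = "degenerate"  # lognormal | gaussian | degenerate
    mean_fraction: dict = field(default_factory=lambda: {s: 1.0 for s in SEGMENTS})
    sd_fraction: dict = field(default_factory=lambda: {s: 0.0 for s in SEGMENTS})
    c0_clinical: float = C_SIN0_CLINICAL
    floor_clinical: float = C_SIN_FLOOR_CLINICAL

    def __post_init__(self):
        if self.family not in ("lognormal", "gaussian", "degenerate"):
            raise VascularSpecError(f"unknown distribution family {self.family!r}")
        for s in SEGMENTS:
            m = self.mean_fraction.get(s)
            sd = self.sd_fraction.get(s)
            if m is None or sd is None:
                raise VascularSpecError(f"distribution spec missing segment {s}")
            if not np.isfinite(m) or not np.isfinite(sd):
                raise VascularSpecError(f"non-finite moments for segment {s}")
            if not 0 < m <= 1:
                raise VascularSpecError(f"mean fraction for segment {s} must be in (0, 1]")
            if sd < 0:
                raise VascularSpecError(f"sd fraction for segment {s} must be >= 0")
            if m * self.c0_clinical < self.floor_clinical:
                raise VascularSpecError(
                    f"mean sinusoid conductance for segment {s} is below the "
                    f"floor {self.floor_clinical} ml/(min.mmHg)"
                )

    def scaled_sd(self, factor: float) -> "SinusoidDistributionSpec":
        """Same means, all sd fractions multiplied by ``factor``."""
        return SinusoidDistributionSpec(
            family=self.family,
            mean_fraction=dict(self.mean_fraction),
            sd_fraction={s: v * factor for s, v in self.sd_fraction.items()},
            c0_clinical=self.c0_clinical,
            floor_clinical=self.floor_clinical,
        )


def _lognormal_params(mean, sd):
    """Underlying normal (mu, sigma) giving arithmetic mean/sd (moment match)."""
    var = sd * sd
    mu = np.log(mean * mean / np.sqrt(mean * mean + var))
    sigma = np.sqrt(np.log(1.0 + var / (mean * mean)))
    return mu, sigma


def sample_sinusoid_conductances(
    spec: SinusoidDistributionSpec,
    segment_of_each_channel: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one conductance per channel, in ml/(min.mmHg).

    ``segment_of_each_channel`` holds segment codes (1..9, as stored on
    sinusoid edges).  Log-normal draws are moment-matched so the sample's
    arithmetic mean and sd converge to the configured values; the
    degenerate family (or sd = 0) returns the mean exactly.  Gaussian
    draws are truncated below at zero conductance-wise by resampling the
    rare non-positive values (the configured sd fractions make these
    vanishingly unlikely).
    """
    seg = np.asarray(segment_of_each_channel)
    out = np.empty(seg.size, dtype=float)
    for code, label in enumerate(SEGMENTS, start=1):
        mask = seg == code
        n = int(mask.sum())
        if n == 0:
            continue
        mean = spec.mean_fraction[label] * spec.c0_clinical
        sd = spec.sd_fraction[label] * spec.c0_clinical
        if spec.family == "degenerate" or sd == 0.0:
            draws = np.full(n, mean)
        elif spec.family == "lognormal":
            mu, sigma = _lognormal_params(mean, sd)
            draws = rng.lognormal(mu, sigma, size=n)
        else:  # gaussian
            draws = rng.normal(mean, sd, size=n)
            bad = draws <= 0
            while bad.any():
                draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = draws <= 0
        out[mask] = draws
    return out


@dataclass(frozen=True)
class CollateralSpec:
    """Lumped portosystemic collateral from the PV inlet to the vena cava."""

    conductance_clinical: float = 0.01 * C_LIVER_CLINICAL
    c_liver_clinical: float = C_LIVER_CLINICAL

    def __post_init__(self):
        if self.conductance_clinical <= 0:
            raise VascularSpecError("collateral conductance must be positive")

    @classmethod
    def from_fraction(cls, fraction: float) -> "CollateralSpec":
        return cls(conductance_clinical=fraction * C_LIVER_CLINICAL)

    @property
    def fraction(self) -> float:
        return self.conductance_clinical / self.c_liver_clinical


@dataclass(frozen=True)
class StageParameters:
    """Complete printed defaults for one disease stage."""

    stage: str
    pv_base_radius_mm: float
    segment_volumes: SegmentVolumeTable
    boundary_conditions: BoundaryConditionSet
    sinusoids: SinusoidDistributionSpec
    collateral: CollateralSpec


def stage_parameters(
    stage: str,
    *,
    family: str | None = None,
    early_seg23_mean_fraction: float = DEFAULT_EARLY_SEG23_MEAN_FRACTION,
    collateral_fraction: float = 0.01,
) -> StageParameters:
    """Stage presets: healthy, early cirrhosis, or advanced cirrhosis.

    Healthy: 5 mmHg PV pressure boundary condition and a homogeneous
    sinusoid field at c0_sin.  Early/advanced: 820 ml/min PV flow boundary
    condition, stage PV radius and segment volumes, and the log-normal
    per-segment conductance distributions (``family`` can switch to the
    Gaussian variant).
    """
    if stage not in STAGES:
        raise VascularSpecError(f"unknown stage {stage!r}; expected one of {STAGES}")
    g1, g23, g48 = _SEGMENT_GROUP_VOLUMES[stage]
    volumes = SegmentVolumeTable.from_groups(g1, g23, g48, stage)
    if stage == "healthy":
        sinusoids = SinusoidDistributionSpec(family=family or "degenerate")
        bcs = BoundaryConditionSet(dp_pv_mmhg=5.0)
    else:
        fields = _STAGE_FIELDS[stage]
        mean_fraction, sd_fraction = {}, {}
        for group, (m, sd) in fields.items():
            if m is None:
                m = early_seg23_mean_fraction
            for s in group:
                mean_fraction[s] = m
                sd_fraction[s] = sd
        sinusoids = SinusoidDistributionSpec(
            family=family or "lognormal",
            mean_fraction=mean_fraction,
            sd_fraction=sd_fraction,
        )
        bcs = BoundaryConditionSet(dp_pv_mmhg=None, q_pv_mlmin=820.0)
    return StageParameters(
        stage=stage,
        pv_base_radius_mm=_PV_BASE_RADIUS_MM[stage],
        segment_volumes=volumes,
        boundary_conditions=bcs,
        sinusoids=sinusoids,
        collateral=CollateralSpec.from_fraction(collateral_fraction),
    )


def attach_collateral(
    network: NetworkTopology,
    collateral: CollateralSpec,
    viscosity: float,
) -> NetworkTopology:
    """Append the collateral edge (PV inlet -> vena cava) in place.

    The edge's nominal geometry is back-computed from its conductance with
    the standard Poiseuille form and a length-to-diameter ratio of 5, so
    velocity and wall shear stress are well defined for it.
    """
    if network.pv_inlet is None:
        raise VascularSpecError("network has no PV inlet to attach a collateral to")
    if network.has_collateral():
        raise VascularSpecError("network already has a collateral edge")
    c_si = units.conductance_to_si(collateral.conductance_clinical)
    d = (640.0 * viscosity * c_si / np.pi) ** (1.0 / 3.0)
    network.tail = np.append(network.tail, network.pv_inlet)
    network.head = np.append(network.head, network.vena_cava)
    network.vessel_class = np.append(
        network.vessel_class, np.int8(CLASS_CODE["collateral"])
    )
    network.generation = np.append(network.generation, np.int32(0))
    network.diameter = np.append(network.diameter, d)
    network.length = np.append(network.length, 5.0 * d)
    network.conductance = np.append(network.conductance, c_si)
    network.viscosity = np.append(network.viscosity, viscosity)
    network.multiplicity = np.append(network.multiplicity, 1.0)
    network.edge_segment = np.append(network.edge_segment, np.int8(0))
    return network


def conductance_diameter_sensitivity(conductance, diameter):
    """Rate of change of Poiseuille conductance with diameter: dc/dd = 4 c / d."""
    c = np.asarray(conductance, dtype=float)
    d = np.asarray(diameter, dtype=float)
    return 4.0 * c / d
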