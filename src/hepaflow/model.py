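"""Whole-liver model and results objects.

:class:`LiverModel` bundles a disease-stage parameter set, a network scale
and the random seeds into one reproducible simulation: ``build()``
synthesizes the vascular graph, ``solve()`` runs the nodal analysis and
returns a :class:`FlowResults` carrying pressures, flows, velocities and
wall shear stress together with reporting and analysis methods.

Desk-scale runs use a conductance-preserving reduction of the 5-million
lobule reference organ: the requested ``lobule_count`` determines the
reduction factor, each lumped sinusoid edge then represents R physical
channels, and tree terminal radii are rescaled by R^(1/3) (see
:func:`hepaflow.vasculature.reduce_scale`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import units
from .cirrhosis import (
    CollateralSpec,
    SinusoidDistributionSpec,
    StageParameters,
    attach_collateral,
    sample_sinusoid_conductances,
    stage_parameters,
)
from .hemodynamics import (
    BoundaryConditionSet,
    FlowSolution,
    assemble_system,
    edge_conductance,
    solve_network,
)
from .rheology import ViscosityModel
from .vasculature import (
    FULL_SCALE_LOBULES,
    CLASS_CODE,
    LiverSpec,
    NetworkTopology,
    allocate_lobules,
    assemble_liver_network,
    build_tree,
    default_tree_specs,
    reduce_scale,
)

__all__ = ["LiverModel", "FlowResults"]


class LiverModel:
    """Lumped-parameter hydraulic model of one liver.

    Parameters
    ----------
    stage : StageParameters or str
        Disease-stage preset (``"healthy"``, ``"early"``, ``"advanced"``)
        or an explicit :class:`~hepaflow.cirrhosis.StageParameters`.
    lobule_count : int
        Number of lobules in the realized network; the reference organ has
        5e6, smaller values trigger the conductance-preserving reduction.
    network_seed, sampling_seed : int
        Seeds for tree growth and for the sinusoid conductance field.
    """

    def __init__(
        self,
        stage: StageParameters | str = "healthy",
        lobule_count: int = 20_000,
        network_seed: int = 0,
        sampling_seed: int = 1,
        viscosity: ViscosityModel | None = None,
        vein_weights: dict | None = None,
        solver_tolerance: float = 1e-10,
        include_collateral: bool = True,
    ):
        if isinstance(stage, str):
            stage = stage_parameters(stage)
        self.stage = stage
        self.network_seed = int(network_seed)
        self.sampling_seed = int(sampling_seed)
        self.viscosity = viscosity or ViscosityModel()
        self.solver_tolerance = solver_tolerance
        self.include_collateral = include_collateral

        trees = default_tree_specs(pv_base_radius_mm=stage.pv_base_radius_mm)
        full = LiverSpec(
            trees=trees,
            lobule_count=FULL_SCALE_LOBULES,
            segment_volumes=stage.segment_volumes,
            **({"vein_weights": vein_weights} if vein_weights else {}),
        )
        self.spec = reduce_scale(full, FULL_SCALE_LOBULES / lobule_count)
        # calibration state: full-scale terminal radii (m) and c_sin scale
        self._terminal_radius_full = {
            name: t.terminal_radius for name, t in trees.items()
        }
        self._c_sin_scale = 1.0
        self._network: NetworkTopology | None = None
        self._sinusoid_samples: np.ndarray | None = None  # clinical, per channel

    # ------------------------------------------------------------------
    @property
    def lobule_count(self) -> int:
        return self.spec.lobule_count

    @property
    def multiplicity(self) -> float:
        return self.spec.sinusoid_multiplicity

    @property
    def radius_scale(self) -> float:
        return self.spec.sinusoid_multiplicity ** (1.0 / 3.0)

    @property
    def network(self) -> NetworkTopology:
        if self._network is None:
            self.build()
        return self._network

    # ------------------------------------------------------------------
    def build(self) -> NetworkTopology:
        """Synthesize the network realization for this model's seeds."""
        rng = np.random.default_rng(self.network_seed)
        spec = self.spec
        alloc = allocate_lobules(
            spec.segment_volumes, spec.lobule_count, spec.vein_weights
        )
        per_segment, per_segment_vein = alloc
        n_triads = 2 * spec.lobule_count
        ha = build_tree(spec.trees["HA"].with_terminals(n_triads), rng)
        pv = build_tree(spec.trees["PV"].with_terminals(n_triads), rng)
        hv_trees = {}
        for vein in ("RHV", "MHV", "LHV"):
            n = sum(per_segment_vein[s].get(vein, 0) for s in per_segment_vein)
            if n > 0:
                hv_trees[vein] = build_tree(spec.trees[vein].with_terminals(n), rng)
        net = assemble_liver_network(
            ha,
            pv,
            hv_trees,
            spec.segment_volumes,
            spec.lobule_count,
            rng,
            allocation=alloc,
        )

        srng = np.random.default_rng(self.sampling_seed)
        sin_mask = net.class_mask("sinusoid")
        self._sinusoid_samples = sample_sinusoid_conductances(
            self.stage.sinusoids, net.edge_segment[sin_mask], srng
        )
        self._apply_geometry(net)
        if self.include_collateral:
            attach_collateral(
                net, self.stage.collateral, self.viscosity.collateral_viscosity()
            )
        self._network = net
        return net

    def _apply_geometry(self, net: NetworkTopology):
        """Populate viscosity, conductance and sinusoid geometry on ``net``.

        Tree and segment-1 edges get the diameter-dependent apparent
        viscosity and the Poiseuille conductance of their own geometry;
        lumped sinusoids get the fixed effective viscosity, the sampled
        conductances (times the scale-reduction multiplicity) and a
        nominal geometry inverted from the per-channel conductance.
        """
        sin_code = CLASS_CODE["sinusoid"]
        col_code = CLASS_CODE["collateral"]
        tree_mask = (net.vessel_class != sin_code) & (net.vessel_class != col_code)

        # tree edge radii follow the (possibly recalibrated) terminal radii
        for name, depth in net.meta["tree_depths"].items():
            mask = net.class_mask(name)
            spec = self.spec.trees[name]
            r0 = spec.base_radius
            # same cap as reduce_scale applies to extreme toy reductions
            rf = min(self._terminal_radius_full[name] * self.radius_scale, 0.5 * r0)
            if depth >= 1:
                gamma = (rf / r0) ** (1.0 / depth)
                radii = r0 * gamma ** net.generation[mask].astype(float)
            else:
                radii = np.full(int(mask.sum()), r0)
            net.diameter[mask] = 2.0 * radii
            net.length[mask] = spec.length_ratio * net.diameter[mask]
        seg1_mask = net.class_mask("segment1")
        if seg1_mask.any():
            d1 = 2.0 * min(
                self._terminal_radius_full["RHV"] * self.radius_scale,
                0.5 * self.spec.trees["RHV"].base_radius,
            )
            net.diameter[seg1_mask] = d1
            net.length[seg1_mask] = self.spec.trees["RHV"].length_ratio * d1

        net.viscosity[tree_mask] = self.viscosity.edge_viscosity(
            net.diameter[tree_mask] / units.UM_TO_M
        )
        net.conductance[tree_mask] = edge_conductance(
            net.diameter[tree_mask], net.length[tree_mask], net.viscosity[tree_mask]
        )

        sin_mask = net.vessel_class == sin_code
        mu_sin = self.viscosity.sinusoid_viscosity()
        c_clin = self._sinusoid_samples * self._c_sin_scale
        c_phys = units.conductance_to_si(c_clin)
        net.viscosity[sin_mask] = mu_sin
        net.conductance[sin_mask] = c_phys * self.multiplicity
        net.multiplicity[sin_mask] = self.multiplicity
        # the lumped channel keeps the healthy reference geometry (diameter
        # and length from c0_sin via c = pi d^4/(128 mu L) with L = 5 d);
        # a varied conductance encodes internal microstructural narrowing,
        # entering velocity through the fixed cross-section and wall shear
        # stress through the conductance term of the WSS formula
        c0_phys = units.conductance_to_si(
            self.stage.sinusoids.c0_clinical * self._c_sin_scale
        )
        d0 = (640.0 * mu_sin * c0_phys / np.pi) ** (1.0 / 3.0)
        net.diameter[sin_mask] = d0
        net.length[sin_mask] = 5.0 * d0

    # ------------------------------------------------------------------
    def update_parameters(
        self,
        terminal_radius_full: dict | None = None,
        c_sin_clinical: float | None = None,
    ):
        """Recalibrate terminal lumen radii (full-scale metres) and/or c_sin.

        ``terminal_radius_full`` keys are ``"HA"``, ``"PV"`` and ``"HV"``
        (the three hepatic-vein trees share one terminal radius).  The
        network topology is kept; geometry-derived conductances are
        recomputed in place.
        """
        if terminal_radius_full:
            for key, val in terminal_radius_full.items():
                if val <= 0:
                    raise ValueError("terminal radii must be positive")
                if key == "HV":
                    for vein in ("RHV", "MHV", "LHV"):
                        self._terminal_radius_full[vein] = val
                elif key in ("HA", "PV"):
                    self._terminal_radius_full[key] = val
                else:
                    raise KeyError(f"unknown terminal radius key {key!r}")
        if c_sin_clinical is not None:
            if c_sin_clinical <= 0:
                raise ValueError("c_sin must be positive")
            self._c_sin_scale = c_sin_clinical / self.stage.sinusoids.c0_clinical
        if self._network is not None:
            self._apply_geometry(self._network)

    # ------------------------------------------------------------------
    def solve(
        self,
        bcs: BoundaryConditionSet | None = None,
        sinusoid_scale: float = 1.0,
        sigma_scale: float | None = None,
        collateral_clinical: float | None = None,
    ) -> "FlowResults":
        """Assemble and solve the nodal system.

        ``sinusoid_scale`` multiplies every lumped sinusoid conductance;
        ``sigma_scale`` instead re-draws the sinusoid field with all sd
        fractions scaled (same sampling seed, common random numbers);
        ``collateral_clinical`` overrides the collateral conductance in
        ml/(min.mmHg).  None of these mutate the stored network.
        """
        net = self.network
        if bcs is None:
            bcs = self.stage.boundary_conditions
        cond = net.conductance
        sin_mask = net.class_mask("sinusoid")
        if sigma_scale is not None:
            srng = np.random.default_rng(self.sampling_seed)
            samples = sample_sinusoid_conductances(
                self.stage.sinusoids.scaled_sd(sigma_scale),
                net.edge_segment[sin_mask],
                srng,
            )
            cond = cond.copy()
            cond[sin_mask] = (
                units.conductance_to_si(samples * self._c_sin_scale) * self.multiplicity
            )
        if sinusoid_scale != 1.0:
            cond = cond.copy()
            cond[sin_mask] *= sinusoid_scale
        if collateral_clinical is not None:
            col_mask = net.class_mask("collateral")
            if not col_mask.any():
                raise ValueError("model has no collateral edge to override")
            cond = cond.copy()
            cond[col_mask] = units.conductance_to_si(collateral_clinical)
        system = assemble_system(net, bcs, conductance=cond)
        solution = solve_network(system, tolerance=self.solver_tolerance)
        return FlowResults(self, net, solution)

    # ------------------------------------------------------------------
    def calibrate(self, problem=None, rng=None):
        """Healthy-liver calibration; see :func:`hepaflow.calibration.calibrate_healthy`."""
        from .calibration import CalibrationProblem, calibrate_healthy

        if problem is None:
            problem = CalibrationProblem()
        return calibrate_healthy(self, problem)


@dataclass
class FlowResults:
    """Results object: solved network state plus derived reports."""

    model: LiverModel
    network: NetworkTopology
    solution: FlowSolution

    # -- headline scalars (clinical units) ------------------------------
    @property
    def q_ha(self) -> float:
        """Hepatic artery inflow, ml/min."""
        return self.solution.q_ha_mlmin

    @property
    def q_pv(self) -> float:
        """Portal vein inflow through the PV base edge, ml/min."""
        return self.solution.q_pv_mlmin

    @property
    def q_liver(self) -> float:
        """Total flow through the liver (HA + PV), ml/min."""
        return self.q_ha + self.q_pv

    @property
    def q_collateral(self) -> float:
        return self.solution.q_collateral_mlmin

    @property
    def q_total(self) -> float:
        """Liver plus collateral flow, ml/min."""
        return self.q_liver + self.q_collateral

    @property
    def dp_pv(self) -> float:
        """Portal vein inlet pressure difference vs the vena cava, mmHg."""
        return self.solution.dp_pv_mmhg

    @property
    def dp_ha(self) -> float:
        return self.solution.dp_ha_mmhg

    @property
    def residual(self) -> float:
        return self.solution.residual

    # -- analysis --------------------------------------------------------
    def major_vessel_summary(self):
        from .analysis import major_vessel_summary

        return major_vessel_summary(self)

    def flow_fractions(self):
        from .analysis import flow_fractions

        return flow_fractions(self)

    def generation_profile(self):
        from .analysis import generation_profile

        return generation_profile(self)

    def segment_metrics(self, reference: "FlowResults | None" = None):
        from .analysis import segment_metrics

        return segment_metrics(self, self.model.stage.segment_volumes, reference)

    def cumulative_flow_fraction(self, by: str = "liver"):
        from .analysis import cumulative_flow_fraction_report

        return cumulative_flow_fraction_report(self, by=by)

    def edge_table(self):
        """Per-edge report (clinical units) as a DataFrame."""
        import pandas as pd

        net, sol = self.network, self.solution
        from .vasculature import SEGMENTS, VESSEL_CLASSES

        return pd.DataFrame(
            {
                "id": np.arange(net.n_edges),
                "vessel_class": np.array(VESSEL_CLASSES)[net.vessel_class],
                "generation": net.generation,
                "segment": np.array(("none",) + SEGMENTS)[net.edge_segment],
                "flow_mlmin": sol.flow_mlmin,
                "velocity_m_s": sol.velocity,
                "wss_pa": sol.wss,
                "dp_mmhg": sol.pressure_mmhg[net.tail] - sol.pressure_mmhg[net.head],
            }
        )

    def save(self, path):
        from .io import save_solution

        save_solution(self, path)

    def summary(self) -> str:
        """Plain-text run summary in clinical units."""
        stage = self.model.stage.stage
        bcs = self.solution.bcs
        pv_bc = (
            f"Δp = {bcs.dp_pv_mmhg:g} mmHg"
            if bcs.pv_mode == "pressure"
            else f"Q = {bcs.q_pv_mlmin:g} ml/min"
        )
        lines = [
            "Liver hydraulic network solution",
            "=" * 48,
            f"stage:               {stage}",
            f"lobules (reduced):   {self.model.lobule_count}  "
            f"(multiplicity {self.model.multiplicity:g})",
            f"nodes / edges:       {self.network.n_nodes} / {self.network.n_edges}",
            f"HA boundary:         Δp = {bcs.dp_ha_mmhg:g} mmHg",
            f"PV boundary:         {pv_bc}",
            "-" * 48,
            f"Q_HA                 {self.q_ha:10.1f} ml/min",
            f"Q_PV                 {self.q_pv:10.1f} ml/min",
            f"Q_liver              {self.q_liver:10.1f} ml/min",
            f"Q_collateral         {self.q_collateral:10.2f} ml/min",
            f"Δp_PV                {self.dp_pv:10.2f} mmHg",
            f"Δp_HA                {self.dp_ha:10.2f} mmHg",
            f"solver residual      {self.residual:10.2e}",
        ]
        return "\n".join(lines)
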