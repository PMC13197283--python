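"""Sparse nodal analysis of the hydraulic network.

Each vessel segment between nodes i and j is a Poiseuille resistor with
hydraulic conductance ``c_ij = pi d^4 / (128 mu L)``; enforcing volume
conservation at every node yields a sparse linear system ``C x = z`` in
the node pressures plus the two unknown inlet flow rates.  The hepatic
artery inlet always carries a fixed pressure difference relative to the
vena cava (the global zero-pressure reference); the portal vein inlet
carries either a fixed pressure difference (healthy liver) or a fixed
volume flow rate through the portal-vein base edge (cirrhosis, where the
splanchnic circulation cannot regulate its outflow), in which case the
PV pressure row is replaced by ``c_base (p_in - p_next) = Q_PV``.

Wall shear stress per vessel is ``WSS = U (32 pi mu^3 / (L c))^{1/4}``
with U the mean velocity Q / (pi d^2 / 4) — algebraically identical to
the Poiseuille form 8 mu U / d when c is the Poiseuille conductance of
the same tube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import MatrixRankWarning, spsolve

from . import units
from .vasculature import NetworkTopology

__all__ = [
    "BoundaryConditionSet",
    "LinearSystem",
    "FlowSolution",
    "SolverError",
    "edge_conductance",
    "assemble_system",
    "solve_network",
    "wall_shear_stress",
]

DEFAULT_DP_HA_MMHG = 77.0
DEFAULT_DP_PV_MMHG = 5.0
DEFAULT_Q_PV_MLMIN = 820.0


class SolverError(RuntimeError):
    """Raised when the nodal system is singular or the solve fails."""


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Inlet boundary conditions against the vena cava reference (0 pressure).

    Exactly one portal-vein mode is active: fixed pressure difference
    ``dp_pv_mmhg`` or fixed volume flow rate ``q_pv_mlmin`` through the PV
    base edge.
    """

    dp_ha_mmhg: float = DEFAULT_DP_HA_MMHG
    dp_pv_mmhg: float | None = DEFAULT_DP_PV_MMHG
    q_pv_mlmin: float | None = None

    def __post_init__(self):
        if self.dp_ha_mmhg <= 0:
            raise ValueError("HA inlet pressure difference must be positive")
        if (self.dp_pv_mmhg is None) == (self.q_pv_mlmin is None):
            raise ValueError("exactly one PV boundary mode (pressure or flow) must be set")

    @property
    def pv_mode(self) -> str:
        return "pressure" if self.dp_pv_mmhg is not None else "flow"

    def with_pv_flow(self, q_mlmin: float) -> "BoundaryConditionSet":
        return BoundaryConditionSet(self.dp_ha_mmhg, None, q_mlmin)


def edge_conductance(diameter, length, viscosity):
    """Poiseuille conductance c = pi d^4 / (128 mu L) (any consistent units)."""
    d = np.asarray(diameter, dtype=float)
    mu = np.asarray(viscosity, dtype=float)
    ln = np.asarray(length, dtype=float)
    if np.any(d <= 0) or np.any(ln <= 0) or np.any(mu <= 0):
        raise ValueError("diameter, length and viscosity must all be positive")
    return np.pi * d**4 / (128.0 * mu * ln)


@dataclass
class LinearSystem:
    """Assembled sparse system ``matrix @ x = rhs``.

    The unknown vector is ``[p_0 .. p_{n-1}, Q_HA, Q_PV(+col)]`` (the HA
    block is absent for networks without an HA inlet).  SI units.
    """

    matrix: sparse.csc_matrix
    rhs: np.ndarray
    network: NetworkTopology
    bcs: BoundaryConditionSet
    conductance: np.ndarray = None
    q_index: dict = field(default_factory=dict)


def assemble_system(
    network: NetworkTopology,
    bcs: BoundaryConditionSet,
    conductance: np.ndarray | None = None,
) -> LinearSystem:
    """Build the nodal continuity system with the selected boundary rows.

    One continuity row per node (the redundant vena cava row is replaced
    by the pressure reference ``p_vc = 0``); one boundary row per inlet.
    ``conductance`` optionally overrides the network's stored edge
    conductances (same SI units) without mutating the network.
    """
    c = network.conductance if conductance is None else np.asarray(conductance, float)
    if np.any(~np.isfinite(c)) or np.any(c <= 0):
        bad = int(np.flatnonzero(~np.isfinite(c) | (c <= 0))[0])
        raise ValueError(f"edge {bad} has non-positive or unset conductance")

    n = network.n_nodes
    t, h = network.tail, network.head
    vc = network.vena_cava

    has_ha = network.ha_inlet is not None
    q_index = {}
    col = n
    if has_ha:
        q_index["HA"] = col
        col += 1
    q_index["PV"] = col
    size = col + 1

    rows = [np.concatenate([t, t, h, h])]
    cols = [np.concatenate([t, h, h, t])]
    vals = [np.concatenate([c, -c, c, -c])]

    # inlet flow unknowns enter the inlet nodes' continuity rows
    if has_ha:
        rows.append(np.array([network.ha_inlet]))
        cols.append(np.array([q_index["HA"]]))
        vals.append(np.array([-1.0]))
    rows.append(np.array([network.pv_inlet]))
    cols.append(np.array([q_index["PV"]]))
    vals.append(np.array([-1.0]))

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    # replace the vena cava continuity row (redundant) with p_vc = 0
    keep = rows != vc
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    rows = np.append(rows, vc)
    cols = np.append(cols, vc)
    vals = np.append(vals, 1.0)

    rhs = np.zeros(size)

    # boundary rows
    extra_r, extra_c, extra_v = [], [], []
    if has_ha:
        r = q_index["HA"]
        extra_r += [r, r]
        extra_c += [network.ha_inlet, vc]
        extra_v += [1.0, -1.0]
        rhs[r] = units.mmhg_to_pa(bcs.dp_ha_mmhg)

    r = q_index["PV"]
    if bcs.pv_mode == "pressure":
        extra_r += [r, r]
        extra_c += [network.pv_inlet, vc]
        extra_v += [1.0, -1.0]
        rhs[r] = units.mmhg_to_pa(bcs.dp_pv_mmhg)
    else:
        base = network.base_edge_index("PV")
        cb = c[base]
        extra_r += [r, r]
        extra_c += [int(network.tail[base]), int(network.head[base])]
        extra_v += [cb, -cb]
        rhs[r] = units.mlmin_to_si(bcs.q_pv_mlmin)

    rows = np.concatenate([rows, np.array(extra_r)])
    cols = np.concatenate([cols, np.array(extra_c)])
    vals = np.concatenate([vals, np.array(extra_v)])

    matrix = sparse.coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsc()
    return LinearSystem(
        matrix=matrix, rhs=rhs, network=network, bcs=bcs, conductance=c, q_index=q_index
    )


@dataclass
class FlowSolution:
    """Solved pressures and derived per-edge quantities (SI internally)."""

    network: NetworkTopology
    bcs: BoundaryConditionSet
    pressure: np.ndarray  # Pa, per node
    flow: np.ndarray  # m^3/s, per edge (positive tail -> head)
    q_ha: float  # m^3/s, inlet unknown (0 if no HA inlet)
    q_pv_inlet: float  # m^3/s, inlet unknown (PV + collateral share)
    residual: float
    conductance: np.ndarray  # SI conductances actually used in the solve

    # -- clinical-unit views ---------------------------------------------
    @property
    def pressure_mmhg(self):
        return units.pa_to_mmhg(self.pressure)

    @property
    def flow_mlmin(self):
        return units.si_to_mlmin(self.flow)

    @property
    def q_ha_mlmin(self):
        return units.si_to_mlmin(self.q_ha)

    @property
    def q_pv_inlet_mlmin(self):
        return units.si_to_mlmin(self.q_pv_inlet)

    @property
    def q_pv_mlmin(self):
        """Flow entering the liver through the PV base edge (excludes collateral)."""
        return float(self.flow_mlmin[self.network.base_edge_index("PV")])

    @property
    def q_collateral_mlmin(self):
        mask = self.network.class_mask("collateral")
        return float(self.flow_mlmin[mask].sum()) if mask.any() else 0.0

    @property
    def dp_pv_mmhg(self):
        return float(self.pressure_mmhg[self.network.pv_inlet])

    @property
    def dp_ha_mmhg(self):
        if self.network.ha_inlet is None:
            return float("nan")
        return float(self.pressure_mmhg[self.network.ha_inlet])

    @property
    def velocity(self):
        """Mean velocity per physical channel, m/s."""
        net = self.network
        area = np.pi * net.diameter**2 / 4.0
        return self.flow / net.multiplicity / area

    @property
    def wss(self):
        return wall_shear_stress(self, self.network)

    def interior_imbalance(self) -> float:
        """Max |net flow| over interior nodes, relative to total inflow."""
        net = self.network
        n = net.n_nodes
        bal = np.zeros(n)
        np.subtract.at(bal, net.tail, self.flow)
        np.add.at(bal, net.head, self.flow)
        interior = np.ones(n, dtype=bool)
        interior[net.vena_cava] = False
        interior[net.pv_inlet] = False
        if net.ha_inlet is not None:
            interior[net.ha_inlet] = False
        total_in = abs(self.q_ha) + abs(self.q_pv_inlet)
        return float(np.abs(bal[interior]).max(initial=0.0) / total_in)


def solve_network(system: LinearSystem, tolerance: float = 1e-10) -> FlowSolution:
    """Direct sparse factorization of the assembled system.

    Raises :class:`SolverError` on a singular matrix or when the relative
    residual ``||Cx - z|| / ||z||`` exceeds ``tolerance``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", MatrixRankWarning)
        try:
            x = spsolve(system.matrix, system.rhs)
        except (MatrixRankWarning, RuntimeError) as exc:
            raise SolverError(f"singular or ill-conditioned nodal system: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("solver returned non-finite values")
    residual = float(
        np.linalg.norm(system.matrix @ x - system.rhs) / np.linalg.norm(system.rhs)
    )
    if residual > tolerance:
        raise SolverError(f"solver residual {residual:.3e} exceeds tolerance {tolerance:.1e}")

    net = system.network
    p = x[: net.n_nodes]
    cond = system.conductance
    flow = cond * (p[net.tail] - p[net.head])
    q_ha = float(x[system.q_index["HA"]]) if "HA" in system.q_index else 0.0
    q_pv = float(x[system.q_index["PV"]])
    return FlowSolution(
        network=net,
        bcs=system.bcs,
        pressure=p,
        flow=flow,
        q_ha=q_ha,
        q_pv_inlet=q_pv,
        residual=residual,
        conductance=cond,
    )


def wall_shear_stress(solution: FlowSolution, network: NetworkTopology | None = None):
    """Per-edge wall shear stress WSS = U (32 pi mu^3 / (L c))^{1/4}, Pa.

    Uses the per-physical-channel conductance (solver conductance divided
    by edge multiplicity) and velocity, so scale-reduced lumped edges
    report the stress in one physical channel.  Zero-flow edges return 0.
    """
    net = network if network is not None else solution.network
    c_phys = solution.conductance / net.multiplicity
    u = solution.velocity
    wss = np.abs(u) * (32.0 * np.pi * net.viscosity**3 / (net.length * c_phys)) ** 0.25
    return np.where(solution.flow == 0.0, 0.0, wss)
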