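"""Stochastic synthesis of the branching liver vascular network.

The whole-organ graph is a union of five rooted trees — hepatic artery (HA)
and portal vein (PV) inflow trees, and right/middle/left hepatic vein
(RHV/MHV/LHV) outflow trees — wired together at the microvascular level:
each lobule owns one central vein and two portal triads, each triad merges
one HA and one PV terminal vessel, and each triad feeds the central vein
through three lumped sinusoid channels (six per lobule).  Central veins of
segment 1 drain straight into the vena cava; all other segments drain into
one of the three hepatic-vein trees according to a configurable
segment-to-vein weight map.  Lobules are apportioned to the nine Couinaud
segments in proportion to segment tissue volume.

Trees are generated generation by generation: the number of daughters at
every branch point is an integer draw from a normal distribution (rounded,
clamped below at 2 so the tree keeps branching), growth stops at the first
generation whose leaf count reaches the requested terminal count, and the
excess leaves are pruned uniformly at random.  Vessel radii follow a
geometric schedule r_k = gamma^k r_0 with gamma chosen so the realized
final generation sits exactly at the terminal radius r_f; lengths are a
fixed multiple of the diameter (the per-tree length ratio).

All geometry is stored in SI units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .units import MM_TO_M, UM_TO_M

__all__ = [
    "VESSEL_CLASSES",
    "CLASS_CODE",
    "NODE_KINDS",
    "KIND_CODE",
    "SEGMENTS",
    "SEGMENT_CODE",
    "TreeSpec",
    "Tree",
    "SegmentVolumeTable",
    "NetworkTopology",
    "LiverSpec",
    "VascularSpecError",
    "compute_generations",
    "radius_schedule",
    "sample_splitting_number",
    "build_tree",
    "allocate_lobules",
    "assemble_liver_network",
    "reduce_scale",
    "default_tree_specs",
    "DEFAULT_VEIN_WEIGHTS",
    "FULL_SCALE_LOBULES",
    "SINUSOID_LENGTH_RATIO",
]

VESSEL_CLASSES = ("HA", "PV", "RHV", "MHV", "LHV", "sinusoid", "collateral", "segment1")
CLASS_CODE = {name: i for i, name in enumerate(VESSEL_CLASSES)}

NODE_KINDS = ("inlet", "junction", "portal_triad", "central_vein", "vena_cava")
KIND_CODE = {name: i for i, name in enumerate(NODE_KINDS)}

SEGMENTS = ("1", "2", "3", "4a", "4b", "5", "6", "7", "8")
SEGMENT_CODE = {name: i + 1 for i, name in enumerate(SEGMENTS)}  # 0 = none

FULL_SCALE_LOBULES = 5_000_000
"""Lobule count of the full-organ model (each lobule has six sinusoid channels)."""

SINUSOID_LENGTH_RATIO = 5.0
"""Length-to-diameter ratio assumed for lumped sinusoid channel geometry."""

MIN_SPLITTING = 2
"""Lower clamp on integer splitting draws; a draw of <= 1 would stall branching."""


class VascularSpecError(ValueError):
    """Raised for invalid tree or network specifications."""


@dataclass(frozen=True)
class TreeSpec:
    """Generation rules for one vascular tree.

    Radii and derived lengths are in metres; splitting statistics and the
    length ratio are dimensionless.
    """

    vessel_class: str
    base_radius: float
    terminal_radius: float
    splitting_mean: float
    splitting_sd: float
    length_ratio: float
    terminal_count: int | None = None
    min_splitting: int = MIN_SPLITTING

    def __post_init__(self):
        if self.vessel_class not in CLASS_CODE:
            raise VascularSpecError(f"unknown vessel class {self.vessel_class!r}")
        if not self.base_radius > self.terminal_radius > 0:
            raise VascularSpecError(
                "require base_radius > terminal_radius > 0, got "
                f"{self.base_radius} and {self.terminal_radius}"
            )
        if self.splitting_mean <= 1:
            raise VascularSpecError("splitting mean must exceed 1")
        if self.splitting_sd < 0:
            raise VascularSpecError("splitting sd must be non-negative")
        if self.length_ratio <= 0:
            raise VascularSpecError("length ratio must be positive")
        if self.terminal_count is not None and self.terminal_count < 1:
            raise VascularSpecError("terminal count must be at least 1")

    def with_terminals(self, n: int) -> "TreeSpec":
        return replace(self, terminal_count=int(n))


def default_tree_specs(pv_base_radius_mm: float = 4.9) -> dict:
    """Tree parameters of the reference human liver model.

    Base/terminal radii, splitting statistics and length ratios for the five
    trees; the PV base radius is stage-dependent (4.9 mm healthy, 6.4 mm
    early cirrhosis, 7.2 mm advanced).  Terminal radii are the calibrated
    healthy-liver optima.  The three hepatic-vein trees share splitting
    statistics and terminal radius but have distinct base radii.
    """
    hv = dict(
        splitting_mean=3.11,
        splitting_sd=1.46,
        length_ratio=5.00,
        terminal_radius=75.3 * UM_TO_M,
    )
    return {
        "HA": TreeSpec(
            "HA",
            base_radius=2.2 * MM_TO_M,
            terminal_radius=2.61 * UM_TO_M,
            splitting_mean=2.76,
            splitting_sd=1.01,
            length_ratio=4.85,
        ),
        "PV": TreeSpec(
            "PV",
            base_radius=pv_base_radius_mm * MM_TO_M,
            terminal_radius=67.5 * UM_TO_M,
            splitting_mean=2.80,
            splitting_sd=0.61,
            length_ratio=5.11,
        ),
        "RHV": TreeSpec("RHV", base_radius=11.7 * MM_TO_M, **hv),
        "MHV": TreeSpec("MHV", base_radius=4.0 * MM_TO_M, **hv),
        "LHV": TreeSpec("LHV", base_radius=6.5 * MM_TO_M, **hv),
    }


# Segment -> hepatic-vein drainage weights.  Fractions of each segment's
# lobules routed to each outflow; segment 1 drains directly to the vena cava.
DEFAULT_VEIN_WEIGHTS = {
    "1": {"VC": 1.0},
    "2": {"LHV": 1.0},
    "3": {"LHV": 1.0},
    "4a": {"MHV": 0.6, "LHV": 0.4},
    "4b": {"MHV": 0.6, "LHV": 0.4},
    "5": {"RHV": 0.5, "MHV": 0.5},
    "6": {"RHV": 1.0},
    "7": {"RHV": 1.0},
    "8": {"RHV": 0.5, "MHV": 0.5},
}


def compute_generations(n_terminal: int, splitting_mean: float) -> int:
    """Nominal branching generation count g = [log N / log s].

    ``[.]`` is rounding to the nearest integer (half away from zero).
    """
    if n_terminal < 1:
        raise VascularSpecError("terminal count must be at least 1")
    if splitting_mean <= 1:
        raise VascularSpecError("splitting mean must exceed 1")
    ratio = math.log(n_terminal) / math.log(splitting_mean)
    return int(math.floor(ratio + 0.5))


def radius_schedule(spec: TreeSpec, generations: int) -> np.ndarray:
    """Per-generation radii r_k = gamma^k r_0 with gamma = (r_f/r_0)^(1/g).

    Returns an array of length ``generations + 1``; the last entry equals
    the terminal radius to floating tolerance.
    """
    if generations < 1:
        raise VascularSpecError("need at least one generation for a radius schedule")
    gamma = (spec.terminal_radius / spec.base_radius) ** (1.0 / generations)
    return spec.base_radius * gamma ** np.arange(generations + 1)


def sample_splitting_number(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    minimum: int = MIN_SPLITTING,
) -> int:
    """One integer daughter count: round a Normal(mean, sd) draw, clamp below."""
    return int(_splitting_draws(rng, mean, sd, 1, minimum)[0])


def _splitting_draws(rng, mean, sd, size, minimum=MIN_SPLITTING):
    if sd < 0:
        raise VascularSpecError("splitting sd must be non-negative")
    draws = np.rint(rng.normal(mean, sd, size=size)).astype(np.int64)
    return np.maximum(draws, minimum)


@dataclass
class Tree:
    """One realized vascular tree.

    Nodes are numbered 0..n_nodes-1 with node 0 the root inlet and node 1
    the first junction; every node at depth k+1 is reached by an edge of
    generation k.  ``parent[i]`` is the parent node of i (-1 for the root).
    All leaves sit at the final depth and have radius ``terminal_radius``.
    """

    spec: TreeSpec
    parent: np.ndarray
    node_depth: np.ndarray
    leaf_nodes: np.ndarray
    depth: int  # number of branching generations actually realized

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_edges(self) -> int:
        return self.parent.size - 1

    def edge_arrays(self):
        """(tail, head, generation, radius) arrays, one edge per non-root node."""
        head = np.arange(1, self.n_nodes, dtype=np.int64)
        tail = self.parent[1:]
        gen = (self.node_depth[1:] - 1).astype(np.int32)
        if self.depth >= 1:
            radii = radius_schedule(self.spec, self.depth)[gen]
        else:
            radii = np.full(gen.size, self.spec.base_radius)
        return tail, head, gen, radii


def build_tree(spec: TreeSpec, rng: np.random.Generator) -> Tree:
    """Grow one stochastic tree with exactly ``spec.terminal_count`` leaves.

    Breadth-first growth: every current leaf branches each round with an
    independently sampled daughter count, until the leaf count first
    reaches or exceeds the target; the excess leaves are then pruned
    uniformly at random (ancestors left childless by pruning are removed
    too, so all remaining terminals sit at the realized final depth).
    """
    if spec.terminal_count is None:
        raise VascularSpecError("tree spec has no terminal count")
    n_target = spec.terminal_count

    parents = [np.array([-1], dtype=np.int64), np.array([0], dtype=np.int64)]
    levels = [np.array([0], dtype=np.int64), np.array([1], dtype=np.int64)]
    n_nodes = 2
    while levels[-1].size < n_target:
        frontier = levels[-1]
        counts = _splitting_draws(
            rng, spec.splitting_mean, spec.splitting_sd, frontier.size, spec.min_splitting
        )
        child_parent = np.repeat(frontier, counts)
        children = np.arange(n_nodes, n_nodes + child_parent.size, dtype=np.int64)
        parents.append(child_parent)
        levels.append(children)
        n_nodes += children.size
        if len(levels) > 64:  # pragma: no cover - defensive
            raise VascularSpecError(
                f"terminal count {n_target} unreachable within 64 generations "
                f"for tree {spec.vessel_class}"
            )

    parent = np.concatenate(parents)
    depth = len(levels) - 2  # branching generations realized (0 for N == 1)

    leaves = levels[-1]
    keep = np.zeros(n_nodes, dtype=bool)
    keep[:2] = True
    kept_leaves = (
        leaves
        if leaves.size == n_target
        else np.sort(rng.choice(leaves, size=n_target, replace=False))
    )
    keep[kept_leaves] = True
    # mark ancestors of kept leaves, deepest level first
    for level in levels[:1:-1]:
        kept_here = level[keep[level]]
        keep[parent[kept_here]] = True

    new_id = np.cumsum(keep) - 1
    parent_kept = parent[keep]
    parent_new = np.where(parent_kept >= 0, new_id[parent_kept], -1)

    node_depth = np.zeros(n_nodes, dtype=np.int32)
    for d, level in enumerate(levels):
        node_depth[level] = d
    node_depth_new = node_depth[keep]

    return Tree(
        spec=spec,
        parent=parent_new,
        node_depth=node_depth_new,
        leaf_nodes=new_id[kept_leaves],
        depth=depth,
    )


@dataclass(frozen=True)
class SegmentVolumeTable:
    """Per-Couinaud-segment tissue volumes (cm^3) for one disease stage."""

    volumes_cm3: dict
    stage: str = "healthy"

    def __post_init__(self):
        missing = set(SEGMENTS) - set(self.volumes_cm3)
        if missing:
            raise VascularSpecError(f"segment volumes missing entries: {sorted(missing)}")
        if any(v <= 0 for v in self.volumes_cm3.values()):
            raise VascularSpecError("segment volumes must be positive")

    @property
    def total_cm3(self) -> float:
        return float(sum(self.volumes_cm3[s] for s in SEGMENTS))

    def fractions(self) -> dict:
        tot = self.total_cm3
        return {s: self.volumes_cm3[s] / tot for s in SEGMENTS}

    @classmethod
    def from_groups(cls, seg1, seg23, seg48, stage):
        """Build from the printed group totals, splitting equally within groups.

        seg23 is the II-III group total; seg48 the IV-VIII group total.
        """
        vols = {"1": float(seg1)}
        for s in ("2", "3"):
            vols[s] = seg23 / 2.0
        for s in ("4a", "4b", "5", "6", "7", "8"):
            vols[s] = seg48 / 6.0
        return cls(vols, stage)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise VascularSpecError("apportionment weights must have positive sum")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(np.int64)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def allocate_lobules(
    segments: SegmentVolumeTable,
    lobule_count: int,
    vein_weights: dict | None = None,
):
    """Apportion lobules to segments (by volume) and to outflow veins.

    Returns ``(per_segment, per_segment_vein)`` where ``per_segment`` maps
    segment label -> lobule count and ``per_segment_vein`` maps segment
    label -> {vein: count} with veins among RHV/MHV/LHV/VC.
    """
    if vein_weights is None:
        vein_weights = DEFAULT_VEIN_WEIGHTS
    missing = set(SEGMENTS) - set(vein_weights)
    if missing:
        raise VascularSpecError(f"vein weight map missing segments: {sorted(missing)}")
    fracs = segments.fractions()
    counts = _largest_remainder(np.array([fracs[s] for s in SEGMENTS]), lobule_count)
    per_segment = dict(zip(SEGMENTS, counts.tolist()))
    per_segment_vein = {}
    for s in SEGMENTS:
        weights = vein_weights[s]
        veins = sorted(weights)
        split = _largest_remainder(np.array([weights[v] for v in veins]), per_segment[s])
        per_segment_vein[s] = dict(zip(veins, split.tolist()))
    return per_segment, per_segment_vein


@dataclass
class NetworkTopology:
    """Whole-liver hydraulic graph as flat node/edge arrays.

    Edges are oriented in the nominal flow direction (inlet towards the
    vena cava); geometry in SI.  ``conductance`` and ``viscosity`` are
    populated by the model layer (:mod:`hepaflow.model`).  ``multiplicity``
    is the number of physical channels a (scale-reduced) edge represents;
    solver conductance includes it, per-channel velocity and wall shear
    stress divide it back out.
    """

    tail: np.ndarray
    head: np.ndarray
    vessel_class: np.ndarray  # int8 codes into VESSEL_CLASSES
    generation: np.ndarray
    diameter: np.ndarray
    length: np.ndarray
    conductance: np.ndarray  # SI, m^3/(s.Pa)
    viscosity: np.ndarray  # Pa.s
    multiplicity: np.ndarray
    edge_segment: np.ndarray  # int8 codes, 0 = none
    node_kind: np.ndarray
    node_segment: np.ndarray
    ha_inlet: int | None
    pv_inlet: int | None
    vena_cava: int
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_kind.size

    @property
    def n_edges(self) -> int:
        return self.tail.size

    def class_mask(self, name: str) -> np.ndarray:
        return self.vessel_class == CLASS_CODE[name]

    def base_edge_index(self, name: str) -> int:
        """Index of the base (generation-0 tree) edge of a major vessel class."""
        idx = np.flatnonzero(self.class_mask(name) & (self.generation == 0))
        if name in ("RHV", "MHV", "LHV"):
            idx = idx[self.head[idx] == self.vena_cava]
        elif name == "HA":
            idx = idx[self.tail[idx] == self.ha_inlet]
        elif name == "PV":
            idx = idx[self.tail[idx] == self.pv_inlet]
        if idx.size != 1:
            raise KeyError(f"no unique base edge for class {name}")
        return int(idx[0])

    def has_collateral(self) -> bool:
        return bool(np.any(self.class_mask("collateral")))

    def nodes_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.n_nodes),
                "kind": np.array(NODE_KINDS)[self.node_kind],
                "segment": np.array(("none",) + SEGMENTS)[self.node_segment],
            }
        )

    def edges_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.n_edges),
                "tail": self.tail,
                "head": self.head,
                "vessel_class": np.array(VESSEL_CLASSES)[self.vessel_class],
                "generation": self.generation,
                "segment": np.array(("none",) + SEGMENTS)[self.edge_segment],
                "diameter_m": self.diameter,
                "length_m": self.length,
                "conductance_si": self.conductance,
                "viscosity_pa_s": self.viscosity,
                "multiplicity": self.multiplicity,
            }
        )

    def validate(self):
        """Connectivity audit: every node must reach the vena cava sink."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = self.n_nodes
        ones = np.ones(self.n_edges)
        adj = coo_matrix((ones, (self.tail, self.head)), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp != 1:
            orphan = int(np.flatnonzero(labels != labels[self.vena_cava])[0])
            raise VascularSpecError(
                f"network is disconnected: node {orphan} cannot reach the vena cava"
            )
        if np.count_nonzero(self.node_kind == KIND_CODE["vena_cava"]) != 1:
            raise VascularSpecError("network must contain exactly one vena cava node")

    def to_graphml(self, path):
        import networkx as nx

        g = nx.DiGraph()
        kinds = np.array(NODE_KINDS)[self.node_kind]
        segs = np.array(("none",) + SEGMENTS)[self.node_segment]
        for i in range(self.n_nodes):
            g.add_node(int(i), kind=str(kinds[i]), segment=str(segs[i]))
        classes = np.array(VESSEL_CLASSES)[self.vessel_class]
        for e in range(self.n_edges):
            g.add_edge(
                int(self.tail[e]),
                int(self.head[e]),
                vessel_class=str(classes[e]),
                generation=int(self.generation[e]),
                diameter=float(self.diameter[e]),
                length=float(self.length[e]),
                conductance=float(self.conductance[e]),
            )
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class LiverSpec:
    """Full problem specification for one network realization.

    ``sinusoid_multiplicity`` is the number of physical sinusoid channels
    each lumped edge represents after scale reduction (1 at full scale);
    terminal radii in the tree specs are already rescaled accordingly.
    """

    trees: dict
    lobule_count: int
    segment_volumes: SegmentVolumeTable
    vein_weights: dict = field(default_factory=lambda: dict(DEFAULT_VEIN_WEIGHTS))
    sinusoid_multiplicity: float = 1.0

    def __post_init__(self):
        if self.lobule_count < 1:
            raise VascularSpecError("lobule count must be at least 1")
        if self.sinusoid_multiplicity < 1:
            raise VascularSpecError("sinusoid multiplicity must be >= 1")


def reduce_scale(spec: LiverSpec, reduction_factor: float) -> LiverSpec:
    """Desk-scale reduction preserving aggregate conductances.

    The lobule count is divided by ``reduction_factor``; each lumped
    sinusoid edge then represents R physical channels (its conductance is
    multiplied by R at build time), and every tree terminal radius is
    scaled by R^(1/3) so the aggregate terminal-layer conductance
    (proportional to N r^3 for length proportional to diameter) is
    preserved.  R is recomputed from the realized integer lobule count so
    the sinusoid aggregate is preserved to machine precision.
    """
    if reduction_factor < 1:
        raise VascularSpecError("reduction factor must be >= 1")
    reduced_lobules = int(round(spec.lobule_count / reduction_factor))
    if reduced_lobules < 1:
        raise VascularSpecError(
            f"reduction factor {reduction_factor} leaves no lobules "
            f"(from {spec.lobule_count})"
        )
    r_exact = spec.lobule_count / reduced_lobules
    radius_scale = r_exact ** (1.0 / 3.0)
    # extreme reductions would push the rescaled terminal radius past the
    # base radius; cap it at half the base (terminal-layer conductance is
    # then no longer preserved, but such scales are toy networks anyway)
    trees = {
        name: replace(
            t,
            terminal_radius=min(
                t.terminal_radius * radius_scale, 0.5 * t.base_radius
            ),
        )
        for name, t in spec.trees.items()
    }
    return replace(
        spec,
        trees=trees,
        lobule_count=reduced_lobules,
        sinusoid_multiplicity=spec.sinusoid_multiplicity * r_exact,
    )


def assemble_liver_network(
    ha: Tree,
    pv: Tree,
    hv_trees: dict,
    segments: SegmentVolumeTable,
    lobule_count: int,
    rng: np.random.Generator,
    vein_weights: dict | None = None,
    allocation=None,
) -> NetworkTopology:
    """Wire the five trees, triads and lumped sinusoids into one graph.

    ``hv_trees`` maps vein name -> Tree for the veins that received at
    least one lobule.  HA and PV trees must each have ``2 * lobule_count``
    terminals (two portal triads per lobule); each hepatic-vein tree must
    have exactly as many terminals as central veins routed to it.
    Sinusoid-edge conductance/diameter/length are left NaN for the model
    layer to populate.
    """
    if allocation is None:
        allocation = allocate_lobules(segments, lobule_count, vein_weights)
    per_segment, per_segment_vein = allocation

    if ha.leaf_nodes.size != 2 * lobule_count or pv.leaf_nodes.size != 2 * lobule_count:
        raise VascularSpecError("HA and PV trees need two terminals per lobule")
    for vein, tree in hv_trees.items():
        need = sum(per_segment_vein[s].get(vein, 0) for s in SEGMENTS)
        if tree.leaf_nodes.size != need:
            raise VascularSpecError(
                f"{vein} tree has {tree.leaf_nodes.size} terminals, needs {need}"
            )

    # ---- node numbering -------------------------------------------------
    # 0: vena cava; then HA nodes; PV nodes minus leaves (merged onto HA
    # leaves, forming the portal triads); HV nodes minus roots (merged onto
    # the vena cava); finally new central-vein nodes for segment 1.
    vc = 0
    offset = 1

    ha_map = np.arange(ha.n_nodes, dtype=np.int64) + offset
    offset += ha.n_nodes
    triad_nodes = ha_map[ha.leaf_nodes]  # index i -> triad for leaf i

    pv_map = np.full(pv.n_nodes, -1, dtype=np.int64)
    pv_is_leaf = np.zeros(pv.n_nodes, dtype=bool)
    pv_is_leaf[pv.leaf_nodes] = True
    n_pv_internal = pv.n_nodes - pv.leaf_nodes.size
    pv_map[~pv_is_leaf] = np.arange(n_pv_internal, dtype=np.int64) + offset
    offset += n_pv_internal
    pv_map[pv.leaf_nodes] = triad_nodes  # merge PV leaf i with HA leaf i

    hv_maps = {}
    for vein in ("RHV", "MHV", "LHV"):
        if vein not in hv_trees:
            continue
        tree = hv_trees[vein]
        m = np.empty(tree.n_nodes, dtype=np.int64)
        m[0] = vc
        m[1:] = np.arange(tree.n_nodes - 1, dtype=np.int64) + offset
        offset += tree.n_nodes - 1
        hv_maps[vein] = m

    n_seg1 = per_segment_vein["1"].get("VC", 0)
    seg1_cv = np.arange(n_seg1, dtype=np.int64) + offset
    offset += n_seg1
    n_nodes = offset

    # ---- central-vein assignment per lobule -----------------------------
    # Lobules ordered by segment, then by vein block inside each segment.
    lobule_segment = np.concatenate(
        [np.full(per_segment[s], SEGMENT_CODE[s], dtype=np.int8) for s in SEGMENTS]
    )
    cv_nodes = np.empty(lobule_count, dtype=np.int64)
    hv_cursor = {vein: 0 for vein in hv_trees}
    seg1_cursor = 0
    pos = 0
    for s in SEGMENTS:
        for vein in sorted(per_segment_vein[s]):
            cnt = per_segment_vein[s][vein]
            if cnt == 0:
                continue
            if vein == "VC":
                cv_nodes[pos : pos + cnt] = seg1_cv[seg1_cursor : seg1_cursor + cnt]
                seg1_cursor += cnt
            else:
                tree = hv_trees[vein]
                take = tree.leaf_nodes[hv_cursor[vein] : hv_cursor[vein] + cnt]
                cv_nodes[pos : pos + cnt] = hv_maps[vein][take]
                hv_cursor[vein] += cnt
            pos += cnt

    # ---- edges ----------------------------------------------------------
    tails, heads, classes, gens, radii, lratios, esegs = [], [], [], [], [], [], []

    def add_tree(tree, node_map, name, flip=False):
        t, h, g, r = tree.edge_arrays()
        t, h = node_map[t], node_map[h]
        if flip:
            t, h = h, t
        tails.append(t)
        heads.append(h)
        classes.append(np.full(t.size, CLASS_CODE[name], dtype=np.int8))
        gens.append(g)
        radii.append(r)
        lratios.append(np.full(t.size, tree.spec.length_ratio))
        esegs.append(np.zeros(t.size, dtype=np.int8))

    add_tree(ha, ha_map, "HA")
    add_tree(pv, pv_map, "PV")
    for vein, tree in hv_trees.items():
        add_tree(tree, hv_maps[vein], vein, flip=True)

    # segment-1 direct drainage: one terminal-HV-calibre vessel per central vein
    if n_seg1:
        hv_spec = next(iter(hv_trees.values())).spec if hv_trees else None
        r_f = hv_spec.terminal_radius if hv_spec else 75.3 * UM_TO_M
        lr = hv_spec.length_ratio if hv_spec else 5.0
        tails.append(seg1_cv)
        heads.append(np.full(n_seg1, vc, dtype=np.int64))
        classes.append(np.full(n_seg1, CLASS_CODE["segment1"], dtype=np.int8))
        gens.append(np.zeros(n_seg1, dtype=np.int32))
        radii.append(np.full(n_seg1, r_f))
        lratios.append(np.full(n_seg1, lr))
        esegs.append(np.full(n_seg1, SEGMENT_CODE["1"], dtype=np.int8))

    # sinusoids: triads 2j and 2j+1 each feed lobule j's central vein thrice
    sin_tail = np.repeat(triad_nodes, 3)
    sin_head = np.repeat(cv_nodes, 6)
    sin_seg = np.repeat(lobule_segment, 6)
    tails.append(sin_tail)
    heads.append(sin_head)
    classes.append(np.full(sin_tail.size, CLASS_CODE["sinusoid"], dtype=np.int8))
    gens.append(np.zeros(sin_tail.size, dtype=np.int32))
    radii.append(np.full(sin_tail.size, np.nan))
    lratios.append(np.full(sin_tail.size, SINUSOID_LENGTH_RATIO))
    esegs.append(sin_seg)

    tail = np.concatenate(tails)
    head = np.concatenate(heads)
    vclass = np.concatenate(classes)
    gen = np.concatenate(gens).astype(np.int32)
    diam = 2.0 * np.concatenate(radii)
    length = diam * np.concatenate(lratios)
    eseg = np.concatenate(esegs)

    # ---- node annotations ----------------------------------------------
    node_kind = np.full(n_nodes, KIND_CODE["junction"], dtype=np.int8)
    node_segment = np.zeros(n_nodes, dtype=np.int8)
    node_kind[vc] = KIND_CODE["vena_cava"]
    ha_inlet = int(ha_map[0])
    pv_inlet = int(pv_map[0])
    node_kind[ha_inlet] = KIND_CODE["inlet"]
    node_kind[pv_inlet] = KIND_CODE["inlet"]
    node_kind[triad_nodes] = KIND_CODE["portal_triad"]
    node_kind[cv_nodes] = KIND_CODE["central_vein"]
    node_segment[triad_nodes] = np.repeat(lobule_segment, 2)
    node_segment[cv_nodes] = lobule_segment

    return NetworkTopology(
        tail=tail,
        head=head,
        vessel_class=vclass,
        generation=gen,
        diameter=diam,
        length=length,
        conductance=np.full(tail.size, np.nan),
        viscosity=np.full(tail.size, np.nan),
        multiplicity=np.ones(tail.size),
        edge_segment=eseg,
        node_kind=node_kind,
        node_segment=node_segment,
        ha_inlet=ha_inlet,
        pv_inlet=pv_inlet,
        vena_cava=vc,
        meta={
            "lobule_count": lobule_count,
            "per_segment": per_segment,
            "per_segment_vein": per_segment_vein,
            "tree_depths": {
                **{t.spec.vessel_class: t.depth for t in (ha, pv)},
                **{v: t.depth for v, t in hv_trees.items()},
            },
        },
    )
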