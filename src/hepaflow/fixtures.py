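"""Small analytically solvable networks for validation.

Each fixture returns a :class:`~hepaflow.vasculature.NetworkTopology`
together with a dict of closed-form expectations (pressures/flows)
computed from elementary series/parallel resistor algebra, independently
of the sparse solver.  Conductances are given directly in ml/(min.mmHg);
geometry is back-filled so velocity and WSS are well defined.
"""

from __future__ import annotations

import numpy as np

from . import units
from .vasculature import CLASS_CODE, KIND_CODE, NetworkTopology

__all__ = ["FIXTURE_KINDS", "manual_network", "fixture_generator"]

FIXTURE_KINDS = (
    "single_edge",
    "series_chain",
    "parallel_pair",
    "symmetric_tree",
    "one_lobule_liver",
)

_DEFAULT_MU = 0.003  # Pa.s, nominal macro-vessel viscosity for fixtures


def manual_network(
    n_nodes: int,
    edges,
    pv_inlet: int,
    vena_cava: int,
    ha_inlet: int | None = None,
    viscosity: float = _DEFAULT_MU,
) -> NetworkTopology:
    """Build a topology from an explicit edge list.

    ``edges`` is a sequence of ``(tail, head, conductance_clinical)`` or
    ``(tail, head, conductance_clinical, vessel_class)`` tuples.  Nominal
    geometry is inverted from each conductance with a length-to-diameter
    ratio of 5.
    """
    tail, head, cond, classes = [], [], [], []
    for e in edges:
        t, h, c = e[0], e[1], e[2]
        cls = e[3] if len(e) > 3 else "PV"
        tail.append(t)
        head.append(h)
        cond.append(units.conductance_to_si(c))
        classes.append(CLASS_CODE[cls])
    tail = np.array(tail, dtype=np.int64)
    head = np.array(head, dtype=np.int64)
    cond = np.array(cond)
    diam = (640.0 * viscosity * cond / np.pi) ** (1.0 / 3.0)

    node_kind = np.full(n_nodes, KIND_CODE["junction"], dtype=np.int8)
    node_kind[vena_cava] = KIND_CODE["vena_cava"]
    node_kind[pv_inlet] = KIND_CODE["inlet"]
    if ha_inlet is not None:
        node_kind[ha_inlet] = KIND_CODE["inlet"]

    return NetworkTopology(
        tail=tail,
        head=head,
        vessel_class=np.array(classes, dtype=np.int8),
        generation=np.zeros(tail.size, dtype=np.int32),
        diameter=diam,
        length=5.0 * diam,
        conductance=cond,
        viscosity=np.full(tail.size, viscosity),
        multiplicity=np.ones(tail.size),
        edge_segment=np.zeros(tail.size, dtype=np.int8),
        node_kind=node_kind,
        node_segment=np.zeros(n_nodes, dtype=np.int8),
        ha_inlet=ha_inlet,
        pv_inlet=pv_inlet,
        vena_cava=vena_cava,
        meta={"fixture": True},
    )


def fixture_generator(kind: str, **params):
    """Return ``(network, expectation)`` for one fixture kind.

    Expectations are in clinical units: flows in ml/min, pressures in mmHg
    relative to the vena cava.
    """
    if kind == "single_edge":
        c = params.get("c", 10.0)
        dp = params.get("dp", 5.0)
        net = manual_network(2, [(0, 1, c)], pv_inlet=0, vena_cava=1)
        return net, {"dp_pv": dp, "q_pv": c * dp}

    if kind == "series_chain":
        cs = list(params.get("cs", (10.0, 20.0, 40.0)))
        dp = params.get("dp", 5.0)
        n = len(cs) + 1
        edges = [(i, i + 1, cs[i]) for i in range(len(cs))]
        net = manual_network(n, edges, pv_inlet=0, vena_cava=n - 1)
        c_eff = 1.0 / sum(1.0 / c for c in cs)
        q = c_eff * dp
        # node pressures: cumulative drops along the chain
        pressures = [dp]
        for c in cs:
            pressures.append(pressures[-1] - q / c)
        return net, {"dp_pv": dp, "q_pv": q, "pressures": pressures}

    if kind == "parallel_pair":
        c1 = params.get("c1", 10.0)
        c2 = params.get("c2", 30.0)
        dp = params.get("dp", 5.0)
        net = manual_network(2, [(0, 1, c1), (0, 1, c2)], pv_inlet=0, vena_cava=1)
        return net, {"dp_pv": dp, "q_pv": (c1 + c2) * dp, "edge_flows": [c1 * dp, c2 * dp]}

    if kind == "symmetric_tree":
        depth = params.get("depth", 2)
        branching = params.get("branching", 2)
        c_edge = params.get("c_edge", 12.0)
        dp = params.get("dp", 5.0)
        # perfect b-ary tree of identical edges; all leaves tied to the sink
        # through identical edges, so flows within a generation are equal.
        edges = []
        nodes = [0]
        next_id = 1
        levels = [[0]]
        for _ in range(depth):
            new = []
            for parent in levels[-1]:
                for _ in range(branching):
                    edges.append((parent, next_id, c_edge))
                    new.append(next_id)
                    next_id += 1
            levels.append(new)
        sink = next_id
        for leaf in levels[-1]:
            edges.append((leaf, sink, c_edge))
        net = manual_network(sink + 1, edges, pv_inlet=0, vena_cava=sink)
        # series of per-generation parallel layers: layer k has b^k (or
        # b^depth for the leaf-sink layer) identical conductances
        layer_counts = [branching**k for k in range(1, depth + 1)] + [branching**depth]
        r_total = sum(1.0 / (n * c_edge) for n in layer_counts)
        q_total = dp / r_total
        per_gen_flow = [q_total / n for n in layer_counts]
        return net, {"dp_pv": dp, "q_pv": q_total, "per_generation_flow": per_gen_flow}

    if kind == "one_lobule_liver":
        # two inlets, two triads, one central vein, six sinusoid channels
        # and an outflow vessel to the vena cava; no closed form recorded —
        # validate against an independently assembled dense system.
        c_ha = params.get("c_ha", 0.5)
        c_pv = params.get("c_pv", 4.0)
        c_sin = params.get("c_sin", 1.0)
        c_out = params.get("c_out", 20.0)
        # nodes: 0 HA inlet, 1 PV inlet, 2 HA junction, 3 PV junction,
        # 4/5 portal triads, 6 central vein, 7 vena cava
        edges = [
            (0, 2, 2 * c_ha, "HA"),
            (2, 4, c_ha, "HA"),
            (2, 5, c_ha, "HA"),
            (1, 3, 2 * c_pv, "PV"),
            (3, 4, c_pv, "PV"),
            (3, 5, c_pv, "PV"),
        ]
        edges += [(4, 6, c_sin, "sinusoid")] * 3
        edges += [(5, 6, c_sin, "sinusoid")] * 3
        edges.append((6, 7, c_out, "RHV"))
        net = manual_network(8, edges, pv_inlet=1, vena_cava=7, ha_inlet=0)
        net.node_kind[4] = KIND_CODE["portal_triad"]
        net.node_kind[5] = KIND_CODE["portal_triad"]
        net.node_kind[6] = KIND_CODE["central_vein"]
        return net, {}

    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
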