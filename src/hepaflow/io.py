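"""Serialization of networks and solutions.

Solutions are written as a directory containing a chunked binary edge
table (Parquet) plus a small JSON summary, so the summary can be loaded
without touching the edge data.  Networks round-trip through CSV or
Parquet two-table (nodes, edges) form, with optional GraphML export.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = 1

__all__ = [
    "save_network",
    "load_network_frames",
    "save_solution",
    "load_solution",
    "SolutionArtifact",
]


def save_network(network, path, fmt: str = "parquet"):
    """Write the node and edge tables (CSV or Parquet) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nodes, edges = network.nodes_frame(), network.edges_frame()
    if fmt == "parquet":
        nodes.to_parquet(path / "nodes.parquet", index=False)
        edges.to_parquet(path / "edges.parquet", index=False)
    elif fmt == "csv":
        nodes.to_csv(path / "nodes.csv", index=False)
        edges.to_csv(path / "edges.csv", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def load_network_frames(path, fmt: str = "parquet"):
    path = Path(path)
    if fmt == "parquet":
        return (
            pd.read_parquet(path / "nodes.parquet"),
            pd.read_parquet(path / "edges.parquet"),
        )
    if fmt == "csv":
        return pd.read_csv(path / "nodes.csv"), pd.read_csv(path / "edges.csv")
    raise ValueError(f"unknown network format {fmt!r}")


def _config_hash(results) -> str:
    model = results.model
    key = json.dumps(
        {
            "stage": model.stage.stage,
            "lobule_count": model.lobule_count,
            "network_seed": model.network_seed,
            "sampling_seed": model.sampling_seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def save_solution(results, path):
    """Persist a :class:`~hepaflow.model.FlowResults` under ``path``.

    Writes ``summary.json`` (inlet flows/pressures, residual, seeds,
    config hash, format version) and ``edges.parquet`` (full per-edge
    state at float64 precision) plus ``pressures.parquet`` for the node
    pressures.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    summary = {
        "format_version": FORMAT_VERSION,
        "stage": results.model.stage.stage,
        "lobule_count": results.model.lobule_count,
        "network_seed": results.model.network_seed,
        "sampling_seed": results.model.sampling_seed,
        "config_hash": _config_hash(results),
        "q_ha_mlmin": results.q_ha,
        "q_pv_mlmin": results.q_pv,
        "q_collateral_mlmin": results.q_collateral,
        "dp_pv_mmhg": results.dp_pv,
        "dp_ha_mmhg": results.dp_ha,
        "residual": results.residual,
    }
    (path / "summary.json").write_text(json.dumps(summary, indent=2))
    edges = results.edge_table()
    edges["conductance_si"] = results.solution.conductance
    edges.to_parquet(path / "edges.parquet", index=False)
    pd.DataFrame({"pressure_pa": results.solution.pressure}).to_parquet(
        path / "pressures.parquet", index=False
    )


class SolutionArtifact:
    """Loaded solution: summary dict plus lazily-loaded tables."""

    def __init__(self, path, summary, edges=None, pressures=None):
        self.path = Path(path)
        self.summary = summary
        self.edges = edges
        self.pressures = pressures


def load_solution(path, summary_only: bool = False) -> SolutionArtifact:
    path = Path(path)
    summary = json.loads((path / "summary.json").read_text())
    version = summary.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"solution format version {version} does not match reader {FORMAT_VERSION}"
        )
    if summary_only:
        return SolutionArtifact(path, summary)
    edges = pd.read_parquet(path / "edges.parquet")
    pressures = np.asarray(pd.read_parquet(path / "pressures.parquet")["pressure_pa"])
    return SolutionArtifact(path, summary, edges, pressures)
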