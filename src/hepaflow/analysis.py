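"""Derived reports: major-vessel summaries, generation profiles, segment
metrics, cumulative flow-fraction curves, collateral sweeps and sinusoid
sensitivity scans.

All tabular outputs are pandas DataFrames in clinical units (ml/min, mmHg,
Pa for wall shear stress).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .vasculature import SEGMENTS, SegmentVolumeTable

logger = logging.getLogger(__name__)

__all__ = [
    "major_vessel_summary",
    "flow_fractions",
    "generation_profile",
    "segment_metrics",
    "cumulative_flow_fraction",
    "cumulative_flow_fraction_report",
    "collateral_sweep",
    "sensitivity_scan",
]

MAJOR_VESSELS = ("HA", "PV", "RHV", "MHV", "LHV")

TISSUE_DENSITY_G_PER_CM3 = 1.0
"""Tissue density used to convert segment volume to mass for perfusion."""


def _base_flow(results, name: str) -> float:
    net = results.network
    if name == "collateral":
        return results.q_collateral
    if name == "segment1":
        mask = net.class_mask("segment1")
        return float(results.solution.flow_mlmin[mask].sum()) if mask.any() else 0.0
    try:
        idx = net.base_edge_index(name)
    except KeyError:
        return 0.0
    return float(results.solution.flow_mlmin[idx])


def major_vessel_summary(results) -> pd.DataFrame:
    """Flows at the base edges of the major vessels plus inlet pressures."""
    rows = []
    for name in MAJOR_VESSELS + ("segment1", "collateral"):
        rows.append(
            {
                "vessel": name,
                "flow_mlmin": _base_flow(results, name),
                "inlet_dp_mmhg": {
                    "HA": results.dp_ha,
                    "PV": results.dp_pv,
                }.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows)


def flow_fractions(results) -> dict:
    """Percent shares of total (liver + collateral) flow per major pathway.

    The inflow shares HA + PV + collateral and the outflow shares
    RHV + MHV + LHV + segment-1 + collateral each sum to 100% (within
    rounding of the stochastic network).
    """
    total = results.q_total
    out = {
        name: 100.0 * _base_flow(results, name) / total
        for name in MAJOR_VESSELS + ("segment1", "collateral")
    }
    return out


def generation_profile(results) -> pd.DataFrame:
    """Mean and range of flow and WSS per (vessel class, generation)."""
    table = results.edge_table()
    grouped = (
        table.groupby(["vessel_class", "generation"], observed=True)
        .agg(
            flow_mean=("flow_mlmin", "mean"),
            flow_min=("flow_mlmin", "min"),
            flow_max=("flow_mlmin", "max"),
            wss_mean=("wss_pa", "mean"),
            wss_min=("wss_pa", "min"),
            wss_max=("wss_pa", "max"),
            n_edges=("flow_mlmin", "size"),
        )
        .reset_index()
    )
    empty = grouped["n_edges"] == 0
    if empty.any():  # pragma: no cover - groupby drops empty groups
        logger.info("omitting %d empty generations", int(empty.sum()))
        grouped = grouped[~empty]
    return grouped


def segment_metrics(
    results,
    volumes: SegmentVolumeTable,
    reference=None,
) -> pd.DataFrame:
    """Per-Couinaud-segment inflow, perfusion and sinusoid WSS.

    Segment inflow is the summed flow through that segment's lumped
    sinusoid channels; perfusion divides by segment mass (volume times a
    1 g/cm^3 tissue density).  When a healthy ``reference`` solution is
    given, the mean sinusoid WSS is also reported as a fold change
    relative to it.
    """
    net = results.network
    sin = net.class_mask("sinusoid")
    seg = net.edge_segment[sin]
    q = results.solution.flow_mlmin[sin]
    wss = results.solution.wss[sin]

    ref_wss = None
    if reference is not None:
        rnet = reference.network
        rsin = rnet.class_mask("sinusoid")
        ref_wss = {}
        for code in range(1, len(SEGMENTS) + 1):
            m = rnet.edge_segment[rsin] == code
            ref_wss[code] = float(reference.solution.wss[rsin][m].mean()) if m.any() else np.nan

    rows = []
    for code, label in enumerate(SEGMENTS, start=1):
        m = seg == code
        flow = float(q[m].sum())
        mass = volumes.volumes_cm3[label] * TISSUE_DENSITY_G_PER_CM3
        mean_wss = float(wss[m].mean()) if m.any() else np.nan
        row = {
            "segment": label,
            "flow_mlmin": flow,
            "perfusion_mlmin_g": flow / mass,
            "wss_mean_pa": mean_wss,
        }
        if ref_wss is not None:
            row["wss_fold_change"] = mean_wss / ref_wss[code]
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_flow_fraction(
    conductances: np.ndarray,
    flows: np.ndarray,
    total_flow: float,
) -> pd.DataFrame:
    """Cumulative flow fraction versus conductance percentile.

    Channels are sorted ascending by conductance (stable sort, so ties
    keep input order); percentile is rank/count in percent and the flow
    axis is the running sum normalized by ``total_flow``.
    """
    c = np.asarray(conductances, dtype=float)
    q = np.asarray(flows, dtype=float)
    order = np.argsort(c, kind="stable")
    cum = np.cumsum(q[order]) / total_flow
    pct = 100.0 * np.arange(1, c.size + 1) / c.size
    return pd.DataFrame(
        {"percentile": pct, "conductance": c[order], "cumulative_flow_fraction": cum}
    )


def cumulative_flow_fraction_report(results, by: str = "liver") -> pd.DataFrame:
    """Whole-liver (``by="liver"``) or per-segment (``by="segment"``) curves.

    Flows are normalized by the total liver flow in both groupings, so a
    segment's curve ends at that segment's share of total flow and the
    whole-liver curve ends at 1.
    """
    net = results.network
    sin = net.class_mask("sinusoid")
    c = net.conductance[sin]
    q = results.solution.flow_mlmin[sin]
    total = results.q_liver
    if by == "liver":
        return cumulative_flow_fraction(c, q, total)
    if by != "segment":
        raise ValueError("by must be 'liver' or 'segment'")
    seg = net.edge_segment[sin]
    frames = []
    for code, label in enumerate(SEGMENTS, start=1):
        m = seg == code
        if not m.any():
            continue
        frame = cumulative_flow_fraction(c[m], q[m], total)
        frame.insert(0, "segment", label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def collateral_sweep(model, c_col_clinical=None) -> pd.DataFrame:
    """Flow-share partition across a sweep of collateral conductances.

    Re-solves the model for each collateral conductance (ml/(min.mmHg))
    and reports the percent shares of total (liver + collateral) flow for
    the inflows, the hepatic veins and the collateral, plus the inlet
    pressure differences.
    """
    from .cirrhosis import COLLATERAL_SWEEP_CLINICAL

    if c_col_clinical is None:
        c_col_clinical = COLLATERAL_SWEEP_CLINICAL
    rows = []
    for c_col in c_col_clinical:
        res = model.solve(collateral_clinical=c_col)
        fracs = res.flow_fractions()
        rows.append(
            {
                "stage": model.stage.stage,
                "c_col_mlmin_mmhg": c_col,
                "c_col_over_c_liver": c_col / model.stage.collateral.c_liver_clinical,
                **{f"frac_{k}": v for k, v in fracs.items()},
                "dp_pv_mmhg": res.dp_pv,
                "dp_ha_mmhg": res.dp_ha,
                "q_total_mlmin": res.q_total,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_scan(
    model,
    perturbations=(-0.05, 0.05),
    vary: str = "mean",
) -> pd.DataFrame:
    """Portal-pressure sensitivity to liver-wide sinusoid changes.

    For each relative perturbation delta the lumped sinusoid conductances
    are multiplied by (1 + delta) (``vary="mean"``) or the sinusoid field
    is re-drawn with all sd fractions scaled by (1 + delta) and the same
    sampling seed (``vary="sigma"``), the model is re-solved under a fixed
    PV inflow, and the percent change of the PV inlet pressure difference
    is reported.  A healthy model's PV inflow is first fixed at its own
    baseline (pressure-BC) solved value.
    """
    bcs = model.stage.boundary_conditions
    if bcs.pv_mode == "pressure":
        baseline_pressure = model.solve()
        bcs = bcs.with_pv_flow(baseline_pressure.q_pv)
    base = model.solve(bcs=bcs)
    dp0 = base.dp_pv
    rows = []
    for delta in perturbations:
        if vary == "mean":
            res = model.solve(bcs=bcs, sinusoid_scale=1.0 + delta)
        elif vary == "sigma":
            res = model.solve(bcs=bcs, sigma_scale=1.0 + delta)
        else:
            raise ValueError("vary must be 'mean' or 'sigma'")
        rows.append(
            {
                "stage": model.stage.stage,
                "vary": vary,
                "perturbation": delta,
                "dp_pv_mmhg": res.dp_pv,
                "dp_pv_change_pct": 100.0 * (res.dp_pv - dp0) / dp0,
            }
        )
    return pd.DataFrame(rows)
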