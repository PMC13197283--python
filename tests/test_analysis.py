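"""Derived reports: fractions, profiles, segment metrics, curves, scans."""

import numpy as np
import pandas as pd
import pytest

from hepaflow.analysis import (
    collateral_sweep,
    cumulative_flow_fraction,
    sensitivity_scan,
)
from hepaflow.model import LiverModel


@pytest.fixture(scope="module")
def healthy_results(small_healthy):
    return small_healthy.solve()


@pytest.fixture(scope="module")
def advanced_results(small_advanced):
    return small_advanced.solve()


# ---------------------------------------------------------------------------
# fractions and conservation
# ---------------------------------------------------------------------------
def test_fraction_sum_rules(healthy_results, advanced_results):
    for res in (healthy_results, advanced_results):
        f = res.flow_fractions()
        inflow = f["HA"] + f["PV"] + f["collateral"]
        outflow = f["RHV"] + f["MHV"] + f["LHV"] + f["segment1"] + f["collateral"]
        assert inflow == pytest.approx(100.0, abs=0.5)
        assert outflow == pytest.approx(100.0, abs=0.5)


def test_major_vessel_summary_conservation(healthy_results):
    t = healthy_results.major_vessel_summary().set_index("vessel")["flow_mlmin"]
    inflow = t["HA"] + t["PV"]
    outflow = t["RHV"] + t["MHV"] + t["LHV"] + t["segment1"]
    assert inflow == pytest.approx(outflow, rel=1e-9)
    assert healthy_results.dp_ha == pytest.approx(77.0, rel=1e-9)


def test_cirrhotic_pv_flow_is_prescribed(advanced_results):
    t = advanced_results.major_vessel_summary().set_index("vessel")["flow_mlmin"]
    assert t["PV"] == pytest.approx(820.0, rel=1e-9)


# ---------------------------------------------------------------------------
# generation profile
# ---------------------------------------------------------------------------
def test_generation_profile_mean_flow_decreases_with_generation(healthy_results):
    prof = healthy_results.generation_profile()
    for cls in ("HA", "PV"):
        means = prof[prof.vessel_class == cls].sort_values("generation")["flow_mean"]
        assert np.all(np.diff(means.to_numpy()) < 0)


def test_advanced_sinusoid_flow_spans_orders_of_magnitude(advanced_results):
    prof = advanced_results.generation_profile()
    sin = prof[prof.vessel_class == "sinusoid"].iloc[0]
    assert sin.flow_max / sin.flow_min > 100.0


# ---------------------------------------------------------------------------
# segment metrics
# ---------------------------------------------------------------------------
def test_segment_flows_partition_total(healthy_results):
    seg = healthy_results.segment_metrics()
    assert seg.flow_mlmin.sum() == pytest.approx(healthy_results.q_liver, rel=1e-9)
    assert np.all(seg.perfusion_mlmin_g > 0)


def test_fold_change_identity_against_self(healthy_results):
    seg = healthy_results.segment_metrics(reference=healthy_results)
    assert seg.wss_fold_change.to_numpy() == pytest.approx(np.ones(9), rel=1e-12)


def test_advanced_fold_changes_reflect_atrophy_hypertrophy(
    advanced_results, healthy_results
):
    seg = advanced_results.segment_metrics(reference=healthy_results).set_index("segment")
    assert seg.loc["6", "wss_fold_change"] < 1.0
    assert seg.loc["7", "wss_fold_change"] < 1.0
    assert seg.loc["2", "wss_fold_change"] > 1.0
    assert seg.loc["3", "wss_fold_change"] > 1.0


# ---------------------------------------------------------------------------
# cumulative flow fraction
# ---------------------------------------------------------------------------
def brute_force_curve(c, q, total):
    order = sorted(range(len(c)), key=lambda i: c[i])
    running, out = 0.0, []
    for i in order:
        running += q[i]
        out.append(running / total)
    return out


def test_cumulative_curve_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    c = rng.lognormal(0, 1, size=100)
    q = rng.uniform(0.1, 2.0, size=100)
    curve = cumulative_flow_fraction(c, q, q.sum())
    assert curve.cumulative_flow_fraction.to_numpy() == pytest.approx(
        np.array(brute_force_curve(list(c), list(q), q.sum())), rel=1e-12
    )
    assert np.all(np.diff(curve.cumulative_flow_fraction) >= 0)
    assert curve.cumulative_flow_fraction.iloc[-1] == pytest.approx(1.0)


def test_homogeneous_channels_give_straight_line(healthy_results):
    curve = healthy_results.cumulative_flow_fraction()
    # homogeneous healthy field: cumulative fraction tracks the percentile
    assert curve.cumulative_flow_fraction.to_numpy() == pytest.approx(
        curve.percentile.to_numpy() / 100.0, abs=0.02
    )


def test_early_curve_lies_above_advanced(small_advanced):
    early = LiverModel("early", lobule_count=1200, network_seed=3, sampling_seed=4)
    ce = early.solve().cumulative_flow_fraction()
    ca = small_advanced.solve().cumulative_flow_fraction()
    grid = np.linspace(5, 95, 19)
    fe = np.interp(grid, ce.percentile, ce.cumulative_flow_fraction)
    fa = np.interp(grid, ca.percentile, ca.cumulative_flow_fraction)
    assert np.mean(fe - fa) > 0
    assert np.mean(fe >= fa) > 0.8


def test_segment_curves_end_at_segment_share(advanced_results):
    curves = advanced_results.cumulative_flow_fraction(by="segment")
    seg = advanced_results.segment_metrics().set_index("segment")
    for label, grp in curves.groupby("segment"):
        share = seg.loc[label, "flow_mlmin"] / advanced_results.q_liver
        assert grp.cumulative_flow_fraction.iloc[-1] == pytest.approx(share, rel=1e-9)


# ---------------------------------------------------------------------------
# collateral sweep and sensitivity
# ---------------------------------------------------------------------------
def test_collateral_sweep_monotonic(small_advanced):
    table = collateral_sweep(small_advanced)
    assert np.all(np.diff(table.frac_collateral) > 0)
    assert np.all(np.diff(table.frac_RHV) < 0)
    # each row satisfies the inflow sum rule
    total = table.frac_HA + table.frac_PV + table.frac_collateral
    assert total.to_numpy() == pytest.approx(np.full(len(table), 100.0), abs=0.5)


def test_sensitivity_zero_perturbation_is_zero(small_advanced):
    t = sensitivity_scan(small_advanced, perturbations=(0.0,))
    assert t.dp_pv_change_pct.iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_sensitivity_sign_consistency(small_advanced, small_healthy):
    for model in (small_advanced, small_healthy):
        t = sensitivity_scan(model, perturbations=(-0.05, 0.05)).set_index("perturbation")
        assert t.loc[-0.05, "dp_pv_change_pct"] > 0
        assert t.loc[0.05, "dp_pv_change_pct"] < 0


def test_sigma_sensitivity_keeps_mean_and_is_small(small_advanced):
    t = sensitivity_scan(small_advanced, perturbations=(-0.05, 0.05), vary="sigma")
    assert np.all(np.abs(t.dp_pv_change_pct) < 1.0)
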