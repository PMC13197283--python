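"""Nodal assembly, solve, conservation and wall shear stress."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import dense_solve
from hepaflow import units
from hepaflow.fixtures import FIXTURE_KINDS, fixture_generator, manual_network
from hepaflow.hemodynamics import (
    BoundaryConditionSet,
    SolverError,
    assemble_system,
    edge_conductance,
    solve_network,
    wall_shear_stress,
)


# ---------------------------------------------------------------------------
# conductance law
# ---------------------------------------------------------------------------
def test_conductance_scaling_laws():
    c0 = edge_conductance(1e-3, 5e-3, 3e-3)
    assert edge_conductance(2e-3, 5e-3, 3e-3) == pytest.approx(16 * c0, rel=1e-12)
    assert edge_conductance(1e-3, 1e-2, 3e-3) == pytest.approx(c0 / 2, rel=1e-12)
    assert edge_conductance(1e-3, 5e-3, 6e-3) == pytest.approx(c0 / 2, rel=1e-12)


@settings(derandomize=True, max_examples=30)
@given(
    d=st.floats(1e-6, 1e-2), ln=st.floats(1e-6, 1.0), mu=st.floats(1e-4, 1e-1)
)
def test_conductance_positive_and_poiseuille(d, ln, mu):
    c = edge_conductance(d, ln, mu)
    assert c > 0
    assert c == pytest.approx(np.pi * d**4 / (128 * mu * ln), rel=1e-12)


def test_conductance_rejects_nonpositive():
    with pytest.raises(ValueError):
        edge_conductance(0.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# fixtures: closed forms and boundary-condition variants
# ---------------------------------------------------------------------------
def test_single_edge_pressure_bc():
    net, exp = fixture_generator("single_edge", c=12.0, dp=5.0)
    sol = solve_network(assemble_system(net, BoundaryConditionSet(dp_pv_mmhg=5.0)))
    assert sol.q_pv_mlmin == pytest.approx(exp["q_pv"], rel=1e-10)


def test_single_edge_flow_bc_recovers_inlet_pressure():
    net, _ = fixture_generator("single_edge", c=12.0)
    bcs = BoundaryConditionSet(dp_pv_mmhg=None, q_pv_mlmin=60.0)
    sol = solve_network(assemble_system(net, bcs))
    assert sol.q_pv_mlmin == pytest.approx(60.0, rel=1e-10)
    assert sol.dp_pv_mmhg == pytest.approx(60.0 / 12.0, rel=1e-10)


def test_series_chain_harmonic_sum():
    cs = (10.0, 25.0, 40.0)
    net, exp = fixture_generator("series_chain", cs=cs, dp=5.0)
    sol = solve_network(assemble_system(net, BoundaryConditionSet(dp_pv_mmhg=5.0)))
    assert sol.q_pv_mlmin == pytest.approx(exp["q_pv"], rel=1e-10)
    assert sol.pressure_mmhg == pytest.approx(np.array(exp["pressures"]), rel=1e-9)


def test_parallel_pair_adds_conductances():
    net, exp = fixture_generator("parallel_pair", c1=7.0, c2=21.0, dp=4.0)
    sol = solve_network(assemble_system(net, BoundaryConditionSet(dp_pv_mmhg=4.0)))
    assert sol.q_pv_inlet_mlmin == pytest.approx(exp["q_pv"], rel=1e-10)
    assert sol.flow_mlmin == pytest.approx(np.array(exp["edge_flows"]), rel=1e-10)


def test_symmetric_tree_generation_flows_equal():
    net, exp = fixture_generator("symmetric_tree", depth=3, branching=2, c_edge=9.0)
    sol = solve_network(assemble_system(net, BoundaryConditionSet(dp_pv_mmhg=5.0)))
    assert sol.q_pv_inlet_mlmin == pytest.approx(exp["q_pv"], rel=1e-9)
    # symmetry: identical flow in every edge of a layer
    q = sol.flow_mlmin
    start = 0
    for n_layer, q_exp in zip((2, 4, 8, 8), exp["per_generation_flow"]):
        layer = q[start : start + n_layer]
        assert layer == pytest.approx(np.full(n_layer, q_exp), rel=1e-9)
        start += n_layer


@pytest.mark.parametrize("kind", FIXTURE_KINDS)
def test_sparse_solver_matches_dense_oracle(kind):
    net, _ = fixture_generator(kind)
    bcs = BoundaryConditionSet(dp_pv_mmhg=5.0)
    sol = solve_network(assemble_system(net, bcs))
    p_dense, q_ha, q_pv = dense_solve(net, bcs)
    assert sol.pressure == pytest.approx(p_dense, rel=1e-9, abs=1e-9)
    assert sol.q_pv_inlet == pytest.approx(q_pv, rel=1e-9)
    if net.ha_inlet is not None:
        assert sol.q_ha == pytest.approx(q_ha, rel=1e-9)


def test_dense_oracle_agreement_flow_bc_one_lobule():
    net, _ = fixture_generator("one_lobule_liver")
    bcs = BoundaryConditionSet(dp_pv_mmhg=None, q_pv_mlmin=15.0)
    sol = solve_network(assemble_system(net, bcs))
    p_dense, q_ha, q_pv = dense_solve(net, bcs)
    assert sol.pressure == pytest.approx(p_dense, rel=1e-9, abs=1e-9)
    assert sol.q_pv_mlmin == pytest.approx(15.0, rel=1e-10)


def test_disconnected_node_raises_solver_error():
    net = manual_network(3, [(0, 1, 5.0)], pv_inlet=0, vena_cava=1)
    with pytest.raises(SolverError):
        solve_network(assemble_system(net, BoundaryConditionSet(dp_pv_mmhg=5.0)))


def test_bcs_require_exactly_one_pv_mode():
    with pytest.raises(ValueError):
        BoundaryConditionSet(dp_pv_mmhg=5.0, q_pv_mlmin=820.0)
    with pytest.raises(ValueError):
        BoundaryConditionSet(dp_pv_mmhg=None, q_pv_mlmin=None)


# ---------------------------------------------------------------------------
# whole-liver solves: conservation, flow BC exactness, monotonicity, WSS
# ---------------------------------------------------------------------------
def test_mass_conservation_whole_liver(small_healthy):
    res = small_healthy.solve()
    assert res.solution.interior_imbalance() < 1e-8
    # global balance: inflow unknowns equal drainage into the vena cava
    net, flow = res.network, res.solution.flow
    into_vc = flow[net.head == net.vena_cava].sum() - flow[net.tail == net.vena_cava].sum()
    total_in = res.solution.q_ha + res.solution.q_pv_inlet
    assert into_vc == pytest.approx(total_in, rel=1e-10)


def test_flow_bc_prescribes_pv_inflow_exactly(small_advanced):
    res = small_advanced.solve()
    assert res.q_pv == pytest.approx(820.0, rel=1e-9)


def test_portal_pressure_monotone_in_sinusoid_conductance(small_advanced):
    dps = [
        small_advanced.solve(sinusoid_scale=k).dp_pv for k in (1.0, 0.8, 0.5, 0.25)
    ]
    assert all(b > a for a, b in zip(dps, dps[1:]))


def test_wss_equals_poiseuille_closed_form(small_healthy):
    res = small_healthy.solve()
    net, sol = res.network, res.solution
    wss = wall_shear_stress(sol, net)
    rng = np.random.default_rng(0)
    idx = rng.choice(net.n_edges, size=200, replace=False)
    expected = 8.0 * net.viscosity[idx] * np.abs(sol.velocity[idx]) / net.diameter[idx]
    assert wss[idx] == pytest.approx(expected, rel=1e-9)


def test_wss_zero_for_zero_flow():
    net, _ = fixture_generator("single_edge", c=10.0)
    sol = solve_network(assemble_system(net, BoundaryConditionSet(dp_pv_mmhg=None, q_pv_mlmin=1.0)))
    sol.flow[:] = 0.0
    assert wall_shear_stress(sol, net).tolist() == [0.0]


def test_ha_wss_exceeds_venous_wss_at_matched_generation(small_healthy):
    res = small_healthy.solve()
    table = res.edge_table()
    prof = table.groupby(["vessel_class", "generation"])["wss_pa"].mean()
    for gen in (0, 1, 2):
        assert prof["HA"][gen] > prof["PV"][gen]
        assert prof["HA"][gen] > prof["RHV"][gen]


def test_solution_units_roundtrip(small_healthy):
    res = small_healthy.solve()
    sol = res.solution
    assert units.si_to_mlmin(units.mlmin_to_si(820.0)) == pytest.approx(820.0)
    assert sol.q_pv_mlmin + sol.q_collateral_mlmin == pytest.approx(
        sol.q_pv_inlet_mlmin, rel=1e-9
    )
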