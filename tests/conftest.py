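"""Shared fixtures and the independent dense-solver oracle.

``dense_solve`` re-derives the nodal equations from scratch with plain
Python loops and ``numpy.linalg.solve`` — deliberately independent of the
package's sparse assembly path — so sparse/dense agreement is a real
cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from hepaflow import units
from hepaflow.calibration import calibrate_healthy, reduced_scale_problem
from hepaflow.model import LiverModel

ACCEPTANCE_LOBULES = 20_000
SMALL_LOBULES = 1_200


def dense_solve(network, bcs):
    """Dense nodal solve: returns (pressures_pa, q_ha_si, q_pv_si)."""
    n = network.n_nodes
    has_ha = network.ha_inlet is not None
    size = n + (2 if has_ha else 1)
    a = np.zeros((size, size))
    z = np.zeros(size)
    vc = network.vena_cava
    for e in range(network.n_edges):
        t = int(network.tail[e])
        h = int(network.head[e])
        c = float(network.conductance[e])
        if t != vc:
            a[t, t] += c
            a[t, h] -= c
        if h != vc:
            a[h, h] += c
            a[h, t] -= c
    col = n
    if has_ha:
        a[network.ha_inlet, col] -= 1.0
        col += 1
    a[network.pv_inlet, col] -= 1.0
    a[vc, vc] = 1.0

    row = n
    if has_ha:
        a[row, network.ha_inlet] += 1.0
        a[row, vc] -= 1.0
        z[row] = units.mmhg_to_pa(bcs.dp_ha_mmhg)
        row += 1
    if bcs.pv_mode == "pressure":
        a[row, network.pv_inlet] += 1.0
        a[row, vc] -= 1.0
        z[row] = units.mmhg_to_pa(bcs.dp_pv_mmhg)
    else:
        base = network.base_edge_index("PV")
        cb = float(network.conductance[base])
        a[row, int(network.tail[base])] += cb
        a[row, int(network.head[base])] -= cb
        z[row] = units.mlmin_to_si(bcs.q_pv_mlmin)

    x = np.linalg.solve(a, z)
    q_ha = x[n] if has_ha else 0.0
    return x[:n], float(q_ha), float(x[-1])


@pytest.fixture(scope="session")
def small_healthy():
    model = LiverModel("healthy", lobule_count=SMALL_LOBULES, network_seed=3, sampling_seed=4)
    return model


@pytest.fixture(scope="session")
def small_advanced():
    model = LiverModel("advanced", lobule_count=SMALL_LOBULES, network_seed=3, sampling_seed=4)
    return model


@pytest.fixture(scope="session")
def calibrated_healthy():
    """Healthy model at acceptance scale, calibrated to the clinical targets."""
    model = LiverModel(
        "healthy", lobule_count=ACCEPTANCE_LOBULES, network_seed=0, sampling_seed=1
    )
    result = calibrate_healthy(model, reduced_scale_problem(seed=0))
    return model, result


@pytest.fixture(scope="session")
def calibrated_radii(calibrated_healthy):
    _, result = calibrated_healthy
    return {
        "HA": result.params["d_term_ha_um"] / 2 * units.UM_TO_M,
        "PV": result.params["d_term_pv_um"] / 2 * units.UM_TO_M,
        "HV": result.params["d_term_hv_um"] / 2 * units.UM_TO_M,
    }


@pytest.fixture(scope="session")
def early_model(calibrated_radii):
    model = LiverModel("early", lobule_count=ACCEPTANCE_LOBULES, network_seed=0, sampling_seed=1)
    model.update_parameters(terminal_radius_full=calibrated_radii)
    return model


@pytest.fixture(scope="session")
def advanced_model(calibrated_radii):
    model = LiverModel(
        "advanced", lobule_count=ACCEPTANCE_LOBULES, network_seed=0, sampling_seed=1
    )
    model.update_parameters(terminal_radius_full=calibrated_radii)
    return model
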