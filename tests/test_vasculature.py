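"""Tree synthesis, lobule allocation and network assembly."""

import math

import numpy as np
import pytest
from scipy import stats

from hepaflow.model import LiverModel
from hepaflow.vasculature import (
    DEFAULT_VEIN_WEIGHTS,
    SEGMENTS,
    SegmentVolumeTable,
    TreeSpec,
    VascularSpecError,
    allocate_lobules,
    assemble_liver_network,
    build_tree,
    compute_generations,
    default_tree_specs,
    radius_schedule,
    reduce_scale,
    sample_splitting_number,
)


@pytest.mark.parametrize(
    "n, s, expected",
    [
        (1000, 10.0, 3),
        (1, 2.8, 0),
        (5_000_000, 3.11, round(math.log(5e6) / math.log(3.11))),
    ],
)
def test_generation_count(n, s, expected):
    assert compute_generations(n, s) == expected


@pytest.mark.parametrize("n, s", [(0, 2.0), (10, 1.0), (10, 0.5)])
def test_generation_count_rejects_invalid(n, s):
    with pytest.raises(VascularSpecError):
        compute_generations(n, s)


def test_radius_schedule_halving():
    g = 4
    spec = TreeSpec("PV", base_radius=1.0, terminal_radius=1.0 / 2**g,
                    splitting_mean=3.0, splitting_sd=0.0, length_ratio=5.0)
    r = radius_schedule(spec, g)
    assert r == pytest.approx(1.0 * 0.5 ** np.arange(g + 1))


def test_radius_schedule_portal_vein_table_values():
    spec = default_tree_specs()["PV"]
    g = compute_generations(10_000_000, spec.splitting_mean)
    r = radius_schedule(spec, g)
    gamma = (67.5e-6 / 4.9e-3) ** (1.0 / g)
    assert r[1] / r[0] == pytest.approx(gamma, rel=1e-12)
    assert r[-1] == pytest.approx(spec.terminal_radius, rel=1e-12)
    assert np.all(np.diff(r) < 0)


def test_tree_spec_rejects_inverted_radii():
    with pytest.raises(VascularSpecError):
        TreeSpec("PV", base_radius=1e-3, terminal_radius=2e-3,
                 splitting_mean=3.0, splitting_sd=0.0, length_ratio=5.0)


def test_splitting_degenerate():
    rng = np.random.default_rng(0)
    assert all(sample_splitting_number(rng, 3.0, 0.0) == 3 for _ in range(10))


def _clamped_round_normal_mean(mean, sd, minimum=2, kmax=30):
    """Closed-form expectation of max(minimum, round(Normal(mean, sd)))."""
    dist = stats.norm(mean, sd)
    total = minimum * dist.cdf(minimum + 0.5)
    for k in range(minimum + 1, kmax):
        total += k * (dist.cdf(k + 0.5) - dist.cdf(k - 0.5))
    total += kmax * (1 - dist.cdf(kmax - 0.5))
    return total


@pytest.mark.parametrize("mean, sd", [(2.76, 1.01), (2.80, 0.61), (3.11, 1.46)])
def test_splitting_sample_mean_matches_clamped_normal(mean, sd):
    rng = np.random.default_rng(42)
    draws = np.array([sample_splitting_number(rng, mean, sd) for _ in range(20_000)])
    assert draws.min() >= 2
    expected = _clamped_round_normal_mean(mean, sd)
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - expected) < 3 * se


def _spec(n, sd=0.0, mean=3.0):
    return TreeSpec("PV", base_radius=1e-3, terminal_radius=1e-5,
                    splitting_mean=mean, splitting_sd=sd, length_ratio=5.0,
                    terminal_count=n)


def test_single_terminal_tree_is_one_edge():
    tree = build_tree(_spec(1), np.random.default_rng(0))
    assert tree.n_edges == 1
    assert tree.leaf_nodes.tolist() == [1]


def test_deterministic_ternary_tree():
    tree = build_tree(_spec(9), np.random.default_rng(0))
    # base edge + 3 + 9: the closed form sum_k s^k
    assert tree.n_edges == 13
    _, _, gen, radii = tree.edge_arrays()
    assert gen.max() == 2
    leaf_radii = radii[gen == 2]
    assert leaf_radii == pytest.approx(np.full(9, 1e-5), rel=1e-12)


def test_regular_tree_edge_count_closed_form():
    for g, s in ((3, 2.0), (4, 3.0)):
        n = int(s**g)
        tree = build_tree(_spec(n, mean=s), np.random.default_rng(1))
        assert tree.n_edges == sum(int(s**k) for k in range(g + 1))


def test_stochastic_tree_hits_terminal_count_and_terminal_radius():
    rng = np.random.default_rng(5)
    tree = build_tree(_spec(500, sd=1.0, mean=2.8), rng)
    assert tree.leaf_nodes.size == 500
    _, _, gen, radii = tree.edge_arrays()
    assert np.all(gen[np.isin(np.arange(1, tree.n_nodes), tree.leaf_nodes)] == tree.depth)
    assert radii[gen == tree.depth] == pytest.approx(np.full(500, 1e-5), rel=1e-9)
    # generations contiguous from 0
    assert sorted(set(gen.tolist())) == list(range(tree.depth + 1))


def test_tree_build_reproducible():
    a = build_tree(_spec(300, sd=1.2, mean=2.76), np.random.default_rng(9))
    b = build_tree(_spec(300, sd=1.2, mean=2.76), np.random.default_rng(9))
    assert np.array_equal(a.parent, b.parent)
    assert np.array_equal(a.leaf_nodes, b.leaf_nodes)


def test_lobule_allocation_proportional_within_one():
    table = SegmentVolumeTable.from_groups(28.0, 242.0, 1248.0, "healthy")
    per_segment, per_vein = allocate_lobules(table, 997)
    assert sum(per_segment.values()) == 997
    fracs = table.fractions()
    for s in SEGMENTS:
        assert abs(per_segment[s] - fracs[s] * 997) <= 1
        assert sum(per_vein[s].values()) == per_segment[s]


def test_vein_weight_map_must_cover_all_segments():
    table = SegmentVolumeTable.from_groups(28.0, 242.0, 1248.0, "healthy")
    bad = {k: v for k, v in DEFAULT_VEIN_WEIGHTS.items() if k != "8"}
    with pytest.raises(VascularSpecError):
        allocate_lobules(table, 100, vein_weights=bad)


def test_single_lobule_wiring_arithmetic():
    model = LiverModel("healthy", lobule_count=1, network_seed=0)
    net = model.build()
    assert int(net.class_mask("sinusoid").sum()) == 6
    assert int((net.node_kind == 2).sum()) == 2  # two portal triads
    net.validate()


def test_network_counts_and_segment1_bypass(small_healthy):
    net = small_healthy.network
    net.validate()
    lob = net.meta["lobule_count"]
    assert int(net.class_mask("sinusoid").sum()) == 6 * lob
    # segment-1 central veins drain straight to the vena cava
    seg1 = net.class_mask("segment1")
    assert seg1.any()
    assert np.all(net.head[seg1] == net.vena_cava)
    # every major vessel class has a unique base edge
    for name in ("HA", "PV", "RHV", "MHV", "LHV"):
        net.base_edge_index(name)


def test_network_build_bit_reproducible():
    kw = dict(lobule_count=400, network_seed=11, sampling_seed=12)
    a = LiverModel("advanced", **kw).build()
    b = LiverModel("advanced", **kw).build()
    assert np.array_equal(a.tail, b.tail)
    assert np.array_equal(a.head, b.head)
    assert np.array_equal(a.conductance, b.conductance)


def test_reduce_scale_preserves_aggregate_sinusoid_conductance():
    from hepaflow.vasculature import FULL_SCALE_LOBULES, LiverSpec

    table = SegmentVolumeTable.from_groups(28.0, 242.0, 1248.0, "healthy")
    spec = LiverSpec(trees=default_tree_specs(), lobule_count=FULL_SCALE_LOBULES,
                     segment_volumes=table)
    reduced = reduce_scale(spec, 100.0)
    assert reduced.lobule_count == FULL_SCALE_LOBULES // 100
    # aggregate = 6 * lobules * multiplicity * c_sin: the lobule-count ratio
    # is exactly compensated by the multiplicity
    assert reduced.lobule_count * reduced.sinusoid_multiplicity == pytest.approx(
        FULL_SCALE_LOBULES, rel=1e-15
    )
    # terminal-layer aggregate conductance ~ N r^3 is preserved
    for name in spec.trees:
        full_r, red_r = spec.trees[name].terminal_radius, reduced.trees[name].terminal_radius
        assert red_r**3 / full_r**3 == pytest.approx(reduced.sinusoid_multiplicity, rel=1e-12)
    assert reduce_scale(spec, 1.0).trees["PV"].terminal_radius == pytest.approx(
        spec.trees["PV"].terminal_radius
    )
    with pytest.raises(VascularSpecError):
        reduce_scale(spec, 1e9)


def test_segment_allocation_matches_volume_fractions(small_advanced):
    net = small_advanced.network
    per_segment = net.meta["per_segment"]
    fracs = small_advanced.stage.segment_volumes.fractions()
    lob = net.meta["lobule_count"]
    for s in SEGMENTS:
        assert abs(per_segment[s] - fracs[s] * lob) <= 1
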