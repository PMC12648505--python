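import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymph3d.metrics import (
    capillary_orientation,
    capillary_stats,
    intensity_by_valve_position,
    intervalve_distances,
    multipoint_length,
    network_density,
    valves_per_layer,
)
from lymph3d.types import (
    Edge,
    NetworkGraph,
    Node,
    SegmentationMask,
    Valve,
    Volume3D,
)

SP = (1.8, 1.8, 1.8)


def _graph_with_edges(edges):
    g = NetworkGraph(spacing_um=SP)
    nid = 0
    for i, (path, cls) in enumerate(edges):
        path = np.asarray(path)
        g.nodes[nid] = Node(nid, tuple(path[0] * 1.8))
        g.nodes[nid + 1] = Node(nid + 1, tuple(path[-1] * 1.8))
        length = float(
            np.linalg.norm(np.diff(path * 1.8, axis=0), axis=1).sum()
        )
        g.edges[i] = Edge(i, nid, nid + 1, path, length, cls)
        nid += 2
    return g


def _straight_path(n, axis, start=(5, 5, 5)):
    p = np.tile(np.asarray(start), (n, 1))
    p[:, axis] = np.arange(start[axis], start[axis] + n)
    return p


class TestNetworkDensity:
    def test_empty_mask(self):
        m = SegmentationMask(np.zeros((10, 10, 10), bool), SP)
        g = NetworkGraph(spacing_um=SP)
        assert network_density(m, g, 1e6) == (0.0, 0.0)

    def test_exact_conservation(self):
        g = _graph_with_edges([(_straight_path(50, 2), "capillary_branch")])
        m = SegmentationMask(np.ones((10, 10, 60), bool), SP)
        sample = 1e7
        vol_d, len_d = network_density(m, g, sample)
        assert len_d == pytest.approx(g.total_length_um() / sample * 1e6)
        assert vol_d == pytest.approx(m.foreground_volume_um3() / sample)

    def test_zero_sample_errors(self):
        m = SegmentationMask(np.ones((4, 4, 4), bool), SP)
        with pytest.raises(ValueError):
            network_density(m, NetworkGraph(spacing_um=SP), 0.0)

    def test_discarded_edges_excluded(self):
        g = _graph_with_edges(
            [
                (_straight_path(50, 2), "capillary_branch"),
                (_straight_path(50, 1), "discarded"),
            ]
        )
        m = SegmentationMask(np.ones((10, 60, 60), bool), SP)
        _, len_d = network_density(m, g, 1e6)
        assert len_d == pytest.approx(49 * 1.8 / 1e6 * 1e6)


class TestCapillaryStats:
    def test_vertical_capillary(self):
        # 100 um long along z starting at z = 40 um
        path = _straight_path(57, 0, start=(22, 5, 5))  # 22*1.8=39.6..
        path[:, 0] = np.arange(22, 79)  # z from 39.6 to 140.4 um
        g = _graph_with_edges([(path, "capillary_branch")])
        ((length, zmin, zmax),) = capillary_stats(g)
        assert length == pytest.approx(56 * 1.8)
        assert zmin == pytest.approx(39.6)
        assert zmax == pytest.approx(140.4)

    def test_links_only_empty(self):
        g = _graph_with_edges([(_straight_path(30, 2), "precollector_link")])
        assert capillary_stats(g) == []

    def test_three_branches(self):
        g = _graph_with_edges(
            [(_straight_path(20, ax), "capillary_branch") for ax in (0, 1, 2)]
        )
        assert len(capillary_stats(g)) == 3


class TestOrientation:
    def test_along_z(self):
        p = np.stack([np.arange(30), np.zeros(30), np.zeros(30)], 1) * 1.8
        assert capillary_orientation(p) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_along_x(self):
        p = np.stack([np.zeros(30), np.zeros(30), np.arange(30)], 1) * 1.8
        roll, pitch, yaw = capillary_orientation(p)
        assert (roll, pitch, yaw) == pytest.approx((0.0, 90.0, 0.0), abs=1e-9)

    def test_45_in_xz_plane(self):
        t = np.arange(40, dtype=float)
        p = np.stack([t, np.zeros(40), t], 1) * 1.8
        _, pitch, _ = capillary_orientation(p)
        assert pitch == pytest.approx(45.0, abs=2.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            capillary_orientation(np.array([[0.0, 0.0, 0.0]]))

    def test_sign_convention_z_nonnegative(self):
        t = np.arange(30, dtype=float)
        up = np.stack([t, t * 0.3, np.zeros(30)], 1)
        down = up[::-1]
        assert capillary_orientation(up) == pytest.approx(
            capillary_orientation(down), abs=1e-9
        )


class TestMultipointLength:
    def test_pythagorean_triples(self):
        pts = [(0, 0, 0), (0, 4, 3), (12, 4, 3)]
        length, rng = multipoint_length(np.array(pts), (1, 1, 1))
        assert length == 17.0
        assert rng == 13.0

    def test_anisotropic_z_step(self):
        pts = [(0, 0, 0), (5, 0, 0)]
        length, rng = multipoint_length(np.array(pts), (6.52, 1.2, 1.2))
        assert length == pytest.approx(32.6)
        assert rng == pytest.approx(32.6)

    def test_single_point(self):
        assert multipoint_length(np.array([(3, 4, 5)]), (1, 1, 1)) == (0.0, 0.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            multipoint_length(np.empty((0, 3)), (1, 1, 1))

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(-50, 50), st.integers(-50, 50), st.integers(-50, 50)
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_length_at_least_range(self, pts):
        length, rng = multipoint_length(np.array(pts), (1.8, 1.8, 1.8))
        assert length >= rng - 1e-9


def _valve(pos, layer=None, edge_id=None, cls="within_capillary"):
    return Valve(
        centroid_um=tuple(pos),
        volume_um3=2e3,
        voxel_count=100,
        position_class=cls,
        layer=layer,
        edge_id=edge_id,
    )


class TestValvesPerLayer:
    def test_no_valves_zero(self):
        g = NetworkGraph(spacing_um=SP)
        out = valves_per_layer([], g, 1e9)
        assert all(out[k]["count"] == 0 for k in (1, 2, 3))

    def test_counts_from_layers(self):
        valves = (
            [_valve((10, 0, 0), layer=1)] * 12
            + [_valve((160, 0, 0), layer=2)] * 6
            + [_valve((240, 0, 0), layer=3)] * 2
        )
        g = NetworkGraph(spacing_um=SP)
        out = valves_per_layer(valves, g, 1e9)
        assert [out[k]["count"] for k in (1, 2, 3)] == [12.0, 6.0, 2.0]
        assert out[1]["count_per_mm3"] == pytest.approx(12.0)

    def test_per_length_uses_layer_edges(self):
        path = _straight_path(100, 2)
        g = _graph_with_edges([(path, "precollector_link")])
        g.edges[0].layer = 2
        out = valves_per_layer([_valve((0, 0, 0), layer=2)], g, 1e9)
        assert out[2]["length_um"] == pytest.approx(99 * 1.8)
        assert out[2]["count_per_mm"] == pytest.approx(1 / (99 * 1.8e-3))


class TestIntervalveDistances:
    def test_two_valves_on_straight_edge(self):
        path = _straight_path(100, 2)  # along x, arc = (i-5)*1.8 from start
        g = _graph_with_edges([(path, "capillary_branch")])
        v1 = _valve((9, 9, (5 + 17) * 1.8), edge_id=0)  # ~30 um along
        v2 = _valve((9, 9, (5 + 50) * 1.8), edge_id=0)  # ~90 um along
        (d,) = intervalve_distances([v1, v2], g)
        assert d == pytest.approx(33 * 1.8, abs=2.0)

    def test_single_valve_contributes_nothing(self):
        g = _graph_with_edges([(_straight_path(50, 2), "capillary_branch")])
        assert intervalve_distances([_valve((9, 9, 30), edge_id=0)], g) == []

    def test_unassigned_ignored(self):
        g = _graph_with_edges([(_straight_path(50, 2), "capillary_branch")])
        vs = [_valve((9, 9, 30), edge_id=None), _valve((9, 9, 60), edge_id=None)]
        assert intervalve_distances(vs, g) == []


class TestIntensityByValvePosition:
    def _setup(self, cap_value=100.0, link_value=10.0):
        branch = _straight_path(60, 2, start=(10, 10, 10))  # x 10..69
        link = np.stack(
            [np.full(60, 10), np.arange(10, 70), np.full(60, 69)], 1
        )
        g = NetworkGraph(spacing_um=SP)
        g.nodes[0] = Node(0, tuple(branch[0] * 1.8))
        g.nodes[1] = Node(1, tuple(branch[-1] * 1.8))
        g.nodes[2] = Node(2, tuple(link[-1] * 1.8))
        for i, (p, cls) in enumerate([(branch, "capillary_branch"), (link, "precollector_link")]):
            length = float(np.linalg.norm(np.diff(p * 1.8, axis=0), axis=1).sum())
            g.edges[i] = Edge(i, i, i + 1, p, length, cls)
        data = np.zeros((80, 80, 80), dtype=np.float32)
        data[tuple(branch.T)] = cap_value
        data[tuple(link.T)] = link_value
        ch2 = Volume3D(data, SP)
        junction = np.array(g.nodes[1].pos_um)
        valve = _valve(tuple(junction + [0, 0, -5]), cls="base_of_capillary")
        return ch2, g, [valve]

    def test_distinct_sides(self):
        ch2, g, valves = self._setup()
        ((up, down),) = intensity_by_valve_position(ch2, g, valves)
        assert up == pytest.approx(100.0, rel=0.05)
        assert down == pytest.approx(10.0, rel=0.05)

    def test_uniform_channel_equal_means(self):
        ch2, g, valves = self._setup(50.0, 50.0)
        ((up, down),) = intensity_by_valve_position(ch2, g, valves)
        assert up == pytest.approx(down)

    def test_non_base_valves_excluded(self):
        ch2, g, valves = self._setup()
        valves[0].position_class = "within_capillary"
        assert intensity_by_valve_position(ch2, g, valves) == []
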