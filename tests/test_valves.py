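import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import ball

from lymph3d.types import Edge, NetworkGraph, Node, SegmentationMask, Valve, Volume3D
from lymph3d.valves import (
    assign_layers,
    attenuate_background,
    ball_opening,
    classify_valve_positions,
    detect_valve_blobs,
)

SP = (1.8, 1.8, 1.8)


def solid_mask(shape):
    return SegmentationMask(np.ones(shape, bool), SP)


class TestBallOpening:
    @pytest.mark.parametrize("radius", [3, 5, 10])
    def test_matches_direct_morphology(self, radius):
        rng = np.random.default_rng(radius)
        data = rng.uniform(0, 100, (64, 64, 64)).astype(np.float32)
        mine = ball_opening(data, radius)
        fp = ball(radius).astype(bool)
        ero = ndimage.grey_erosion(data, footprint=fp, mode="constant", cval=np.inf)
        oracle = ndimage.grey_dilation(ero, footprint=fp, mode="constant", cval=-np.inf)
        np.testing.assert_array_equal(mine, oracle)

    def test_opening_below_image(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 50, (32, 32, 32)).astype(np.float32)
        assert np.all(ball_opening(data, 4) <= data + 1e-5)


class TestAttenuateBackground:
    def test_constant_inside_mask_zeroed(self):
        v = Volume3D(np.full((40, 40, 40), 55.0, dtype=np.float32), SP)
        out = attenuate_background(v, solid_mask((40, 40, 40)), 18.0)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-4)

    def test_small_ball_retained_at_contrast(self):
        # bright ball radius 8 um (< 18 um SE) on flat background
        data = np.full((64, 64, 64), 20.0, dtype=np.float32)
        zz, yy, xx = np.meshgrid(*[np.arange(64)] * 3, indexing="ij")
        blob = (zz - 32) ** 2 + (yy - 32) ** 2 + (xx - 32) ** 2 <= (8 / 1.8) ** 2
        data[blob] = 120.0
        out = attenuate_background(Volume3D(data, SP), solid_mask((64, 64, 64)), 18.0)
        assert out.data[32, 32, 32] == pytest.approx(100.0, abs=1.0)

    def test_thick_slab_suppressed(self):
        # slab thicker than the 36 um ball diameter survives the opening
        data = np.zeros((64, 64, 64), dtype=np.float32)
        data[20:45, :, :] = 90.0  # 25 voxels = 45 um thick
        out = attenuate_background(Volume3D(data, SP), solid_mask((64, 64, 64)), 18.0)
        assert abs(out.data[32, 32, 32]) < 1.0

    def test_outside_mask_zero(self):
        data = np.full((40, 40, 40), 70.0, dtype=np.float32)
        m = np.zeros((40, 40, 40), bool)
        m[10:30, 10:30, 10:30] = True
        out = attenuate_background(Volume3D(data, SP), SegmentationMask(m, SP), 18.0)
        assert np.all(out.data[~m] == 0.0)

    def test_radius_below_voxel_errors(self):
        v = Volume3D(np.zeros((8, 8, 8)), SP)
        with pytest.raises(ValueError):
            attenuate_background(v, solid_mask((8, 8, 8)), 1.0)


def _blob_volume(radius_um, shape=(64, 64, 64), value=200.0):
    """Enhanced-style image: a bright ball on zero background."""
    data = np.zeros(shape, dtype=np.float32)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = np.array(shape) // 2
    blob = (
        ((zz - c[0]) * 1.8) ** 2 + ((yy - c[1]) * 1.8) ** 2 + ((xx - c[2]) * 1.8) ** 2
    ) <= radius_um**2
    data[blob] = value
    return Volume3D(data, SP), int(blob.sum())


class TestDetectValveBlobs:
    def test_single_blob_detected_volume_close(self):
        # sphere of ~5e3 um^3 -> radius ~10.6 um
        r = (3 * 5000 / (4 * np.pi)) ** (1 / 3)
        vol, n_vox = _blob_volume(r)
        valves = detect_valve_blobs(vol, solid_mask(vol.shape))
        assert len(valves) == 1
        true_vol = n_vox * vol.voxel_volume_um3
        assert valves[0].volume_um3 == pytest.approx(true_vol, rel=0.2)
        assert valves[0].centroid_um == pytest.approx(
            tuple(np.array(vol.shape) // 2 * 1.8), abs=2.0
        )

    def test_too_small_rejected(self):
        r = (3 * 500 / (4 * np.pi)) ** (1 / 3)  # 500 um^3
        vol, _ = _blob_volume(r)
        assert detect_valve_blobs(vol, solid_mask(vol.shape)) == []

    def test_too_large_rejected(self):
        r = (3 * 2e4 / (4 * np.pi)) ** (1 / 3)  # 2e4 um^3
        vol, _ = _blob_volume(r, shape=(72, 72, 72))
        assert detect_valve_blobs(vol, solid_mask(vol.shape)) == []

    def test_constant_image_no_valves(self):
        vol = Volume3D(np.full((48, 48, 48), 30.0, dtype=np.float32), SP)
        assert detect_valve_blobs(vol, solid_mask(vol.shape)) == []

    def test_zero_image_no_valves(self):
        vol = Volume3D(np.zeros((32, 32, 32), dtype=np.float32), SP)
        assert detect_valve_blobs(vol, solid_mask(vol.shape)) == []

    def test_deterministic(self):
        r = (3 * 5000 / (4 * np.pi)) ** (1 / 3)
        vol, _ = _blob_volume(r)
        a = detect_valve_blobs(vol, solid_mask(vol.shape))
        b = detect_valve_blobs(vol, solid_mask(vol.shape))
        assert [v.centroid_um for v in a] == [v.centroid_um for v in b]
        assert [v.volume_um3 for v in a] == [v.volume_um3 for v in b]

    def test_sensitivity_out_of_range(self):
        vol = Volume3D(np.zeros((16, 16, 16)), SP)
        with pytest.raises(ValueError):
            detect_valve_blobs(vol, solid_mask((16, 16, 16)), sensitivity=1.5)

    def test_volume_gate_property(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 300, (48, 48, 48)).astype(np.float32)
        valves = detect_valve_blobs(
            Volume3D(data, SP), solid_mask((48, 48, 48)), mask_erosion_vox=0
        )
        for v in valves:
            assert 1e3 <= v.volume_um3 <= 1e4


def _line_graph():
    """One capillary branch (along x) joined to one precollector link."""
    g = NetworkGraph(spacing_um=SP)
    # branch from (10,10,10) to (10,10,120) vox; link continues to (10,120,120)
    n_b = 111
    branch = np.stack([np.full(n_b, 10), np.full(n_b, 10), np.arange(10, 121)], 1)
    n_l = 111
    link = np.stack([np.full(n_l, 10), np.arange(10, 121), np.full(n_l, 120)], 1)
    g.nodes[0] = Node(0, tuple(branch[0] * 1.8))
    g.nodes[1] = Node(1, tuple(branch[-1] * 1.8))
    g.nodes[2] = Node(2, tuple(link[-1] * 1.8))
    g.edges[0] = Edge(0, 0, 1, branch, 110 * 1.8, "capillary_branch")
    g.edges[1] = Edge(1, 1, 2, link, 110 * 1.8, "precollector_link")
    return g


def _valve_at(pos_um):
    return Valve(centroid_um=tuple(pos_um), volume_um3=2e3, voxel_count=100)


class TestClassifyValvePositions:
    def test_mid_branch_within_capillary(self):
        g = _line_graph()
        v = _valve_at((18.0, 18.0, 120.0))  # mid-branch
        (out,) = classify_valve_positions([v], g)
        assert out.position_class == "within_capillary"
        assert out.edge_id == 0

    def test_near_junction_base_of_capillary(self):
        g = _line_graph()
        junction = np.array(g.nodes[1].pos_um)
        v = _valve_at(tuple(junction + [0, 0, -10]))  # 10 um from the joint
        (out,) = classify_valve_positions([v], g)
        assert out.position_class == "base_of_capillary"

    def test_on_link_far_from_junction(self):
        g = _line_graph()
        v = _valve_at((18.0, 120.0, 216.0))  # 100+ um along the link
        (out,) = classify_valve_positions([v], g)
        assert out.position_class == "precollector"

    def test_layer3_link_is_collector(self):
        g = _line_graph()
        g.edges[1].layer = 3
        v = _valve_at((18.0, 120.0, 216.0))
        (out,) = classify_valve_positions([v], g)
        assert out.position_class == "collector"

    def test_far_valve_unassigned(self):
        g = _line_graph()
        v = _valve_at((200.0, 400.0, 400.0))
        (out,) = classify_valve_positions([v], g)
        assert out.position_class == "unassigned"

    def test_empty_graph_all_unassigned(self):
        g = NetworkGraph(spacing_um=SP)
        (out,) = classify_valve_positions([_valve_at((10, 10, 10))], g)
        assert out.position_class == "unassigned"


class TestAssignLayers:
    def test_valve_layers(self):
        valves = [
            _valve_at((140.0, 0, 0)),
            _valve_at((240.0, 0, 0)),
            _valve_at((150.0, 0, 0)),  # boundary -> deeper band
            _valve_at((209.9, 0, 0)),
        ]
        out = assign_layers(valves)
        assert [v.layer for v in out] == [1, 3, 2, 2]

    def test_edge_layer_uses_median_z(self):
        g = _line_graph()  # all z = 18 um -> layer 1
        out = assign_layers(g)
        assert all(e.layer == 1 for e in out.iter_edges())

    def test_unsorted_bands_error(self):
        with pytest.raises(ValueError):
            assign_layers([], z_bands_um=(210.0, 150.0))
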