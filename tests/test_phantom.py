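import numpy as np
import pytest
from scipy import ndimage

from lymph3d.phantom import (
    PhantomParams,
    SpecEdge,
    PhantomSpec,
    analytic_metrics,
    build_network_spec,
    interior_valve_arcs,
    render_channel2,
    render_volume,
)


class TestInteriorValveArcs:
    def test_fixed_spacing_enumeration(self):
        # 30 um spacing on a 150 um edge -> interior arcs 30, 60, 90, 120
        assert interior_valve_arcs(150.0, 30.0) == [30.0, 60.0, 90.0, 120.0]

    def test_margin_respected(self):
        arcs = interior_valve_arcs(150.0, 30.0, margin_um=35.0)
        assert arcs == [60.0, 90.0]

    def test_too_short_edge_empty(self):
        assert interior_valve_arcs(25.0, 30.0) == []


class TestBuildNetworkSpec:
    def test_empty_case(self):
        spec = build_network_spec(PhantomParams(include_plexus=False), seed=0)
        assert spec.edges == [] and spec.valves == []
        am = analytic_metrics(spec)
        assert am.length_density_mm_per_mm3 == 0.0
        assert am.volume_density == 0.0
        assert am.valve_density_per_mm3 == 0.0

    def test_deterministic(self):
        p = PhantomParams()
        a = build_network_spec(p, seed=3)
        b = build_network_spec(p, seed=3)
        assert len(a.edges) == len(b.edges)
        for ea, eb in zip(a.edges, b.edges):
            np.testing.assert_array_equal(ea.points_um, eb.points_um)
        assert [v.arc_um for v in a.valves] == [v.arc_um for v in b.valves]

    def test_capillary_count_and_structure(self):
        spec = build_network_spec(PhantomParams(), seed=1)
        caps = [e for e in spec.edges if e.kind == "capillary"]
        assert len(caps) == PhantomParams().n_capillaries
        # every capillary's deep end joins a plexus node; the tip is blind
        for e in caps:
            u, v = spec.edge_endpoints[e.id]
            tip = spec.node_pos[v]
            assert tip[0] < PhantomParams().plexus_depth_um  # toward surface

    def test_centerlines_inside_box(self):
        spec = build_network_spec(PhantomParams(), seed=2)
        box = np.asarray(spec.box_um)
        for e in spec.edges:
            assert (e.points_um >= -1e-9).all()
            assert (e.points_um <= box + 1e-9).all()

    def test_valve_arcs_within_edges(self):
        spec = build_network_spec(PhantomParams(), seed=2)
        lengths = {e.id: e.length_um for e in spec.edges}
        for v in spec.valves:
            assert 0 < v.arc_um < lengths[v.edge_id]

    def test_box_too_small_errors(self):
        with pytest.raises(ValueError):
            build_network_spec(
                PhantomParams(box_um=(100.0, 100.0, 100.0), n_capillaries=50), seed=0
            )


class TestRenderVolume:
    def test_noiseless_two_level(self):
        p = PhantomParams(
            include_collector=False,
            n_rungs=0,
            n_capillaries=0,
            background=0.0,
            depth_gradient_per_um=0.0,
            noise_sigma=0.0,
            n_distractors=0,
        )
        spec = build_network_spec(p, seed=0)
        # single straight tube, no valves
        spec.edges = [
            SpecEdge(0, np.array([[100.0, 100.0, 50.0], [100.0, 100.0, 300.0]]), 20.0, "precollector")
        ]
        spec.edge_endpoints = {0: (0, 1)}
        spec.node_pos = {0: np.array([100.0, 100.0, 50.0]), 1: np.array([100.0, 100.0, 300.0])}
        spec.valves = []
        vol, gt = render_volume(spec, (1.8, 1.8, 1.8))
        assert set(np.unique(vol.data)) <= {0.0, p.vessel_intensity}
        assert set(np.unique(gt.label_volume)) == {0, 1}

    def test_determinism_bit_exact(self, small_phantom):
        spec, vol, _ = small_phantom
        vol2, _ = render_volume(spec, (1.8, 1.8, 1.8))
        np.testing.assert_array_equal(vol.data, vol2.data)

    def test_label_volume_noise_free(self, small_phantom):
        spec, vol, gt = small_phantom
        # labels enumerate {bg, vessel, valve, distractor} only
        assert set(np.unique(gt.label_volume)) <= {0, 1, 2, 3}

    def test_valve_label_components_match_truth(self, small_phantom):
        spec, vol, gt = small_phantom
        _, n = ndimage.label(gt.label_volume == 2, structure=np.ones((3, 3, 3)))
        assert n == len(gt.true_valves) == len(spec.valves)

    def test_vessel_network_connected(self):
        spec = build_network_spec(PhantomParams(n_distractors=0), seed=1)
        _, gt = render_volume(spec)
        fg = (gt.label_volume == 1) | (gt.label_volume == 2)
        _, n = ndimage.label(fg, structure=np.ones((3, 3, 3)))
        assert n == 1  # capillaries all join the plexus

    def test_ellipsoid_volume_recorded(self, small_phantom):
        spec, _, gt = small_phantom
        a, b, c = spec.params.valve_semi_axes_um
        expected = 4 / 3 * np.pi * a * b * c
        for v in gt.true_valves:
            assert v.volume_um3 == pytest.approx(expected)

    def test_coarse_spacing_warns(self):
        spec = build_network_spec(PhantomParams(), seed=0)
        with pytest.warns(UserWarning, match="coarser"):
            render_volume(spec, (30.0, 30.0, 30.0))

    def test_raster_volume_close_to_analytic(self):
        # single tube: rasterized foreground within 5% of capsule volume
        p = PhantomParams(include_plexus=False, noise_sigma=0.0, n_distractors=0)
        spec = build_network_spec(p, seed=0)
        spec.edges = [
            SpecEdge(0, np.array([[100.0, 100.0, 40.0], [100.0, 100.0, 500.0]]), 20.0, "precollector")
        ]
        spec.edge_endpoints = {0: (0, 1)}
        spec.node_pos = {0: spec.edges[0].points_um[0], 1: spec.edges[0].points_um[-1]}
        vol, gt = render_volume(spec, (1.8, 1.8, 1.8))
        raster = (gt.label_volume > 0).sum() * vol.voxel_volume_um3
        analytic = np.pi * 20**2 * 460 + 4 / 3 * np.pi * 20**3  # capsule with caps
        assert raster == pytest.approx(analytic, rel=0.05)


class TestAnalyticMetrics:
    def test_single_tube_densities(self):
        p = PhantomParams(include_plexus=False)
        spec = build_network_spec(p, seed=0)
        spec.edges = [
            SpecEdge(0, np.array([[500.0, 500.0, 0.0], [500.0, 500.0, 1000.0]]), 10.0, "precollector")
        ]
        spec.box_um = (1000.0, 1000.0, 1000.0)
        am = analytic_metrics(spec)
        assert am.length_density_mm_per_mm3 == pytest.approx(1.0)
        assert am.volume_density == pytest.approx(np.pi * 100 * 1000 / 1e9, rel=1e-6)

    def test_valve_density_count_over_volume(self):
        p = PhantomParams(include_plexus=False)
        spec = build_network_spec(p, seed=0)
        spec.box_um = (1000.0, 1000.0, 1000.0)
        edge = SpecEdge(0, np.array([[500.0, 0.0, 500.0], [500.0, 1000.0, 500.0]]), 10.0, "precollector")
        spec.edges = [edge]
        from lymph3d.phantom import SpecValve

        spec.valves = [
            SpecValve(0, float(a), edge.point_at(a)[0], np.array([0, 1.0, 0]), (8, 6, 6), "precollector")
            for a in np.linspace(4, 996, 210)
        ]
        am = analytic_metrics(spec)
        assert am.valve_density_per_mm3 == pytest.approx(210.0)

    def test_zero_box_errors(self):
        spec = build_network_spec(PhantomParams(include_plexus=False), seed=0)
        spec.box_um = (0.0, 10.0, 10.0)
        with pytest.raises(ValueError):
            analytic_metrics(spec)

    def test_default_phantom_layer_design(self):
        """The default phantom mirrors decreasing valve density with depth."""
        spec = build_network_spec(PhantomParams(), seed=1)
        am = analytic_metrics(spec)
        counts = [am.valves_per_layer[k]["count"] for k in (1, 2, 3)]
        ratios = [am.valves_per_layer[k]["count_per_mm"] for k in (1, 2, 3)]
        assert counts[0] > counts[1] > counts[2]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_capillary_share_near_a_third(self):
        am = analytic_metrics(build_network_spec(PhantomParams(), seed=1))
        assert 0.2 < am.capillary_length_density_share < 0.45


def test_channel2_bright_on_capillaries(small_phantom):
    spec, _, _ = small_phantom
    ch2 = render_channel2(spec, (1.8, 1.8, 1.8))
    p = spec.params
    vals = set(np.unique(ch2.data))
    assert p.channel2_capillary in vals
    assert p.channel2_other in vals
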