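import numpy as np
import pytest

from lymph3d.types import SegmentationMask, Volume3D

SPACING = (1.8, 1.8, 1.8)


def capsule_mask(shape, segments, radius_vox):
    """Boolean mask of capsules (in voxel units) — shared geometry helper."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], -1).astype(float)
    m = np.zeros(shape, bool)
    for p0, p1 in segments:
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        ab = p1 - p0
        t = np.clip(((pts - p0) @ ab) / max(ab @ ab, 1e-9), 0, 1)
        d = np.linalg.norm(pts - (p0 + t[..., None] * ab), axis=-1)
        m |= d <= radius_vox
    return m


@pytest.fixture
def tube_mask():
    m = capsule_mask((20, 20, 60), [((10, 10, 5), (10, 10, 55))], 4)
    return SegmentationMask(m, SPACING)


@pytest.fixture
def y_mask():
    c = (25, 25, 25)
    arms = [(c, (25, 25, 47)), (c, (25, 44, 14)), (c, (25, 6, 14))]
    return SegmentationMask(capsule_mask((50, 50, 50), arms, 4), SPACING)


@pytest.fixture
def h_mask():
    segs = [
        ((20, 30, 10), (20, 10, 5)),
        ((20, 30, 10), (20, 50, 5)),
        ((20, 30, 45), (20, 10, 85)),
        ((20, 30, 45), (20, 50, 85)),
        ((20, 30, 10), (20, 30, 45)),
    ]
    return SegmentationMask(capsule_mask((40, 60, 90), segs, 4), SPACING)


@pytest.fixture
def torus_mask():
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in (30, 60, 60)], indexing="ij")
    d = np.sqrt((np.sqrt((yy - 30.0) ** 2 + (xx - 30.0) ** 2) - 20) ** 2 + (zz - 15.0) ** 2)
    return SegmentationMask(d <= 4, SPACING)


@pytest.fixture
def small_phantom():
    """A reduced phantom for fast end-to-end tests (not the default suite)."""
    from lymph3d.phantom import PhantomParams, build_network_spec, render_volume

    params = PhantomParams(
        box_um=(320.0, 320.0, 320.0),
        n_capillaries=4,
        plexus_inset_um=70.0,
        n_rungs=0,
        include_collector=False,
        n_distractors=1,
    )
    spec = build_network_spec(params, seed=7)
    volume, gt = render_volume(spec)
    return spec, volume, gt


def flat_volume(value=100.0, shape=(24, 24, 24), spacing=SPACING):
    return Volume3D(np.full(shape, float(value), dtype=np.float32), spacing)
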