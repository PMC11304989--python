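import numpy as np
import pytest

from nodulefpr.preprocess import (
    PlacementError,
    PreprocessConfig,
    ROI,
    extract_roi,
    filter_scans,
    normalize_intensity,
    oversample_positives,
    resample_volume,
    sample_negatives,
)
from nodulefpr.simulate import generate_phantom_scan, random_layout
from nodulefpr.volumes import AnnotationRecord, Volume


def test_config_roi_shape():
    cfg = PreprocessConfig()
    assert cfg.roi_shape == (15, 48, 48)  # 30/2 slices, 30/0.625 in-plane
    with pytest.raises(ValueError):
        PreprocessConfig(hu_window=(400, -1000))


def test_resample_dims_and_identity(rng):
    vol = Volume(rng.normal(size=(100, 100, 100)).astype(np.float32),
                 spacing=(1.0, 1.0, 1.0))
    out = resample_volume(vol, (2.0, 0.625, 0.625))
    assert out.data.shape == (50, 160, 160)
    assert out.spacing == (2.0, 0.625, 0.625)
    assert out.origin == vol.origin
    # already at target spacing: identity on lattice points
    same = resample_volume(out, (2.0, 0.625, 0.625))
    assert np.allclose(same.data, out.data)


def test_resample_preserves_constants():
    vol = Volume(np.full((20, 20, 20), 3.5, dtype=np.float32), (1.0, 1.0, 1.0))
    out = resample_volume(vol, (0.8, 1.3, 2.1))
    assert np.allclose(out.data, 3.5)
    with pytest.raises(ValueError):
        resample_volume(vol, (0.0, 1.0, 1.0))


def test_normalize_window_endpoints():
    data = np.array([[[-1000.0, 400.0, -300.0, 1000.0, -2000.0]]])
    out = normalize_intensity(Volume(data, (1, 1, 1)))
    assert out.data.flatten() == pytest.approx([-1.0, 1.0, 0.0, 1.0, -1.0])


def test_normalize_monotone(rng):
    vals = np.sort(rng.uniform(-1200, 600, size=50)).reshape(1, 1, 50)
    out = normalize_intensity(Volume(vals, (1, 1, 1)))
    assert np.all(np.diff(out.data.flatten()) >= 0)


def test_extract_roi_default_shape_and_determinism(hu_volume):
    nvol = normalize_intensity(hu_volume)
    center = (20.0, 20.0, 16.0)
    roi_a = extract_roi(nvol, center)
    roi_b = extract_roi(nvol, center)
    assert roi_a.patch.shape == (15, 48, 48)
    assert np.array_equal(roi_a.patch, roi_b.patch)
    assert roi_a.patch.min() >= -1.0 and roi_a.patch.max() <= 1.0


def test_extract_roi_corner_padding(hu_volume):
    nvol = normalize_intensity(hu_volume)
    roi = extract_roi(nvol, (0.0, 0.0, 0.0))
    n_pad = np.sum(roi.patch == -1.0)
    assert n_pad > 0
    # the out-of-volume octant is entirely pad-valued
    assert np.all(roi.patch[:7, :24, :24] == -1.0)


def test_extract_roi_far_outside_raises(hu_volume):
    with pytest.raises(PlacementError):
        extract_roi(normalize_intensity(hu_volume), (500.0, 500.0, 500.0))


def test_extract_roi_commutes_with_voxel_translation(hu_volume):
    """Shifting the volume by whole voxels shifts the extraction window."""
    nvol = normalize_intensity(hu_volume)
    center = (20.0, 20.0, 16.0)
    roi = extract_roi(nvol, center)
    shifted = Volume(np.roll(nvol.data, (0, 4, 4), axis=(0, 1, 2)),
                     nvol.spacing, nvol.origin)
    roi_shifted = extract_roi(shifted, (20.0 + 4 * 0.625, 20.0 + 4 * 0.625, 16.0))
    assert np.array_equal(roi.patch, roi_shifted.patch)


def test_sample_negatives_count_and_nonoverlap():
    layout = random_layout("p", seed=8, n_nodules=2, grid=(16, 64, 64))
    vol, anns = generate_phantom_scan(layout, grid=(16, 64, 64))
    nvol = normalize_intensity(vol)
    negs = sample_negatives(nvol, anns, n=200, seed=3, roi_size_mm=30.0)
    assert len(negs) == 200
    half = 15.0
    for cand in negs:
        for ann in anns:
            # closest point of the ROI box to the truth center is outside
            # the truth's bounding sphere
            delta = np.abs(np.subtract(cand.center_world, ann.center_world))
            closest = np.maximum(delta - half, 0.0)
            assert np.linalg.norm(closest) > ann.diameter_mm / 2
    again = sample_negatives(nvol, anns, n=200, seed=3, roi_size_mm=30.0)
    assert [c.center_world for c in negs] == [c.center_world for c in again]


def test_sample_negatives_on_nodule_free_scan():
    layout = random_layout("p", seed=12, n_nodules=0, grid=(16, 64, 64))
    vol, anns = generate_phantom_scan(layout, grid=(16, 64, 64))
    negs = sample_negatives(normalize_intensity(vol), anns, n=1000, seed=0)
    assert len(negs) == 1000


def test_oversample_positives_counts(blob_rois):
    n_pos = sum(r.label == "positive" for r in blob_rois)
    n_neg = len(blob_rois) - n_pos
    out = oversample_positives(blob_rois, 250, seed=0)
    assert sum(r.label == "positive" for r in out) == 250 * n_pos
    assert sum(r.label != "positive" for r in out) == n_neg
    assert oversample_positives(blob_rois, 1) == list(blob_rois)
    with pytest.raises(ValueError):
        oversample_positives(blob_rois, 0)


def test_filter_scans_geometry_rules():
    uniform = {"slice_thickness_mm": 2.0,
               "z_positions": list(np.arange(0, 40, 2.0))}
    thick = {"slice_thickness_mm": 3.0,
             "z_positions": list(np.arange(0, 60, 3.0))}
    z = list(np.arange(0, 40, 2.0))
    z.remove(20.0)  # missing slice: doubled gap
    gappy = {"slice_thickness_mm": 2.0, "z_positions": z}
    jitter = {"slice_thickness_mm": 2.0,
              "z_positions": [0.0, 2.0, 4.01, 6.0]}
    kept = filter_scans([uniform, thick, gappy, jitter])
    assert kept == [uniform]
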