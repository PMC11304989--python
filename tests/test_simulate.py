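import numpy as np
import pytest
from skimage.measure import label as cc_label

from nodulefpr.simulate import (
    DEFAULT_SPACING,
    DegenerateShapeError,
    LayoutError,
    NoduleSpec,
    ScanLayout,
    default_phantom_layouts,
    generate_clinical_scan,
    generate_nodule_mask,
    generate_phantom_scan,
    phantom_nodule_catalogue,
    propose_candidates,
    random_layout,
)
from nodulefpr.volumes import world_to_voxel

SPACING = (2.0, 0.625, 0.625)


def test_spherical_mask_volume_matches_analytic():
    mask = generate_nodule_mask("spherical", 5.0, SPACING)
    voxel_volume = np.prod(SPACING)
    analytic = 4.0 / 3.0 * np.pi * 2.5**3
    assert mask.sum() * voxel_volume == pytest.approx(analytic, rel=0.15)


def test_spherical_mask_flip_invariant():
    mask = generate_nodule_mask("spherical", 8.0, SPACING)
    for axis in range(3):
        assert np.array_equal(mask, np.flip(mask, axis=axis))


def test_spiculated_exceeds_central_sphere():
    # brute-force voxel counts of the two masks
    spic = generate_nodule_mask("spiculated", 10.0, SPACING, seed=3)
    zz, yy, xx = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2) * s for n, s in zip(spic.shape, SPACING)],
        indexing="ij",
    )
    core = zz**2 + yy**2 + xx**2 <= (0.35 * 10.0) ** 2
    assert spic.sum() > core.sum()
    assert np.all(spic[core])


@pytest.mark.parametrize("family", ["spherical", "elliptical", "lobulated", "spiculated"])
def test_mask_bounding_box_within_limit(family):
    d = 12.0
    mask = generate_nodule_mask(family, d, SPACING, seed=5)
    for extent, s in zip(mask.shape, SPACING):
        assert extent * s <= 1.5 * d + 2 * s  # one voxel slack per side


def test_degenerate_diameter_raises():
    with pytest.raises(DegenerateShapeError):
        generate_nodule_mask("spherical", 1.0, SPACING)


def test_empty_layout_scan_is_pure_background():
    layout = ScanLayout(scan_id="empty", nodules=[], noise_hu=10.0, seed=4)
    vol, anns = generate_phantom_scan(layout, grid=(16, 64, 64))
    assert anns == []
    tissues = np.array([-1000.0, -850.0, 40.0, 50.0])
    deviation = np.min(np.abs(vol.data[..., None] - tissues), axis=-1)
    # max |N(0, sigma)| over ~65k voxels concentrates near 4.2 sigma
    assert deviation.max() <= 5 * layout.noise_hu


def test_nodule_core_density_fidelity():
    layout = random_layout("p", seed=11, n_nodules=1, grid=(16, 64, 64))
    layout.nodules[0] = NoduleSpec("spherical", 10.0, 100.0,
                                   layout.nodules[0].center_world)
    vol, anns = generate_phantom_scan(layout, grid=(16, 64, 64))
    k, j, i = (int(round(c)) for c in world_to_voxel(vol, anns[0].center_world))
    core = vol.data[k - 1 : k + 2, j - 3 : j + 4, i - 3 : i + 4]
    assert abs(core.mean() - 100.0) <= 40.0


def test_phantom_scan_deterministic():
    layout = random_layout("p", seed=2, n_nodules=2, grid=(12, 48, 48))
    a, _ = generate_phantom_scan(layout, grid=(12, 48, 48))
    b, _ = generate_phantom_scan(layout, grid=(12, 48, 48))
    assert np.array_equal(a.data, b.data)


def test_overlapping_nodules_rejected():
    spec = NoduleSpec("spherical", 10.0, 100.0, (30.0, 30.0, 15.0))
    layout = ScanLayout("bad", nodules=[spec, spec])
    with pytest.raises(LayoutError):
        generate_phantom_scan(layout, grid=(16, 64, 64))


def test_clinical_scan_annotation_count_and_determinism():
    vol, anns = generate_clinical_scan(seed=9, difficulty=1.0, n_nodules=3,
                                       grid=(12, 48, 48))
    assert len(anns) == 3
    vol2, _ = generate_clinical_scan(seed=9, difficulty=1.0, n_nodules=3,
                                     grid=(12, 48, 48))
    assert np.array_equal(vol.data, vol2.data)


def test_clinical_difficulty_adds_mimic_structures():
    """Clinical mode carries more distinct intra-pulmonary structures above
    −500 HU than a phantom scan of the same seed (majority of seeds; the
    count is restricted to the lung interior to keep the chest wall out)."""
    from scipy.ndimage import binary_erosion

    from nodulefpr.simulate import lung_region

    grid = (16, 64, 64)
    interior = binary_erosion(lung_region(grid), iterations=3)
    wins = 0
    for seed in range(10):
        layout = random_layout("p", seed=seed, n_nodules=2, grid=grid)
        phantom, _ = generate_phantom_scan(layout, grid=grid)
        clinical, _ = generate_clinical_scan(seed=seed, difficulty=1.0,
                                             n_nodules=2, grid=grid)
        n_phantom = cc_label((phantom.data > -500) & interior).max()
        n_clinical = cc_label((clinical.data > -500) & interior).max()
        wins += n_clinical > n_phantom
    assert wins >= 7


def test_clinical_difficulty_zero_stays_plain():
    vol, _ = generate_clinical_scan(seed=3, difficulty=0.0, n_nodules=1,
                                    grid=(12, 48, 48))
    # no texture: parenchyma voxels stay near their base density
    lung = (vol.data > -950) & (vol.data < -700)
    assert np.std(vol.data[lung]) < 3 * 22.0  # noise only, no 60-HU texture


def test_catalogue_has_48_entries():
    cat = phantom_nodule_catalogue()
    assert len(cat) == 48
    assert len(set(cat)) == 48


def test_default_layouts_fit_and_are_reproducible():
    layouts = default_phantom_layouts(n_scans=5, seed=0, grid=(12, 48, 48))
    again = default_phantom_layouts(n_scans=5, seed=0, grid=(12, 48, 48))
    assert [l.scan_id for l in layouts] == [l.scan_id for l in again]
    for la, lb in zip(layouts, again):
        for na, nb in zip(la.nodules, lb.nodules):
            assert na.center_world == nb.center_world


def test_propose_candidates_truth_inclusion():
    layout = random_layout("p", seed=5, n_nodules=2, grid=(16, 64, 64))
    vol, anns = generate_phantom_scan(layout, grid=(16, 64, 64))
    cands = propose_candidates(vol, anns, n_per_scan=50, sensitivity=1.0, seed=1)
    assert len(cands) == 50
    for ann in anns:
        hits = [
            c for c in cands
            if np.linalg.norm(np.subtract(c.center_world, ann.center_world))
            <= ann.diameter_mm / 2
        ]
        assert len(hits) >= 1
    # sensitivity 0: nothing is labeled positive
    cands0 = propose_candidates(vol, anns, n_per_scan=50, sensitivity=0.0, seed=1)
    assert all(c.label == "negative" for c in cands0)


def test_propose_candidates_at_reference_count():
    layout = random_layout("p", seed=6, n_nodules=2, grid=(16, 64, 64))
    vol, anns = generate_phantom_scan(layout, grid=(16, 64, 64))
    cands = propose_candidates(vol, anns, n_per_scan=750, sensitivity=1.0, seed=2)
    assert len(cands) == 750
    assert sum(c.label == "positive" for c in cands) >= 2


def test_shape_families_separable_by_radius_statistic():
    """A trivial radius-spread statistic tells spheres from spiculated masks.

    Sanity floor for learnability: if a hand statistic separates the
    families, a convolutional classifier has signal to work with.
    """

    def spread(mask, spacing):
        zz, yy, xx = np.meshgrid(
            *[(np.arange(n) - (n - 1) / 2) * s for n, s in zip(mask.shape, spacing)],
            indexing="ij",
        )
        r = np.sqrt(zz**2 + yy**2 + xx**2)[mask]
        return r.max() / r.mean()

    rng = np.random.default_rng(0)
    correct = 0
    for i in range(100):
        family = "spherical" if i % 2 == 0 else "spiculated"
        d = float(rng.uniform(6, 16))
        mask = generate_nodule_mask(family, d, SPACING, seed=int(rng.integers(2**31)))
        predicted = "spherical" if spread(mask, SPACING) < 1.7 else "spiculated"
        correct += predicted == family
    assert correct / 100 > 0.9
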