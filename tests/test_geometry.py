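import collections

import numpy as np
import pytest

from rhizoct import geometry as geo
from rhizoct.phantom import generate_phantom
from rhizoct.volume_io import LabelVolume, PORE, ROOT, SOLID

from conftest import desk_phantom_spec, make_cylinder_labels


# ---------------------------------------------------------------- distances
def test_face_adjacent_voxel_is_one_voxel_away():
    labels = np.full((3, 3, 3), SOLID, dtype=np.uint8)
    labels[1, 1, 1] = ROOT
    lv = LabelVolume(data=labels, voxel_size=16.0)
    dist = geo.distance_from_root(lv)
    assert dist[1, 1, 1] == 0.0
    assert dist[1, 1, 2] == pytest.approx(16.0)
    assert dist[0, 0, 0] == pytest.approx(16.0 * np.sqrt(3))


def test_all_root_volume_has_zero_distance():
    lv = LabelVolume(data=np.full((3, 3, 3), ROOT, dtype=np.uint8), voxel_size=16.0)
    assert geo.distance_from_root(lv).max() == 0.0


def test_no_root_directs_to_unplanted_path():
    lv = LabelVolume(data=np.zeros((3, 3, 3), dtype=np.uint8), voxel_size=16.0)
    with pytest.raises(geo.NoRootError, match="unplanted"):
        geo.distance_from_root(lv)


def test_cylinder_distance_matches_radial_geometry(cylinder_labels):
    """Distance ≈ radial distance − root radius, within one voxel diagonal."""
    lv = cylinder_labels
    dist = geo.distance_from_root(lv)
    nz, ny, nx = lv.shape
    yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2.0, np.arange(nx) - (nx - 1) / 2.0, indexing="ij")
    radial_um = np.sqrt(yy**2 + xx**2) * lv.voxel_size
    analytic = np.maximum(radial_um - 500.0, 0.0)
    mid = dist[nz // 2]
    tol = lv.voxel_size * np.sqrt(3)
    assert np.abs(mid - analytic).max() <= tol


# --------------------------------------------------------------- shell masks
def test_shell_masks_partition_soil_to_outer_edge(cylinder_labels):
    dist = geo.distance_from_root(cylinder_labels)
    masks = geo.shell_masks(dist, (0.0, 1.0, 2.0))
    union = np.zeros(cylinder_labels.shape, dtype=bool)
    for m in masks:
        assert not (union & m).any()  # disjoint
        union |= m
    beyond = dist >= 2000.0
    root = cylinder_labels.mask(ROOT)
    assert (union | beyond | root).all()
    assert not (union & root).any()


def test_half_open_band_convention():
    # a voxel exactly at 1 mm belongs to the 1-2 mm band
    labels = np.full((1, 1, 130), SOLID, dtype=np.uint8)
    labels[0, 0, 0] = ROOT
    lv = LabelVolume(data=labels, voxel_size=100.0)
    dist = geo.distance_from_root(lv)
    masks = geo.shell_masks(dist, (0.0, 1.0, 2.0))
    assert dist[0, 0, 10] == pytest.approx(1000.0)
    assert not masks[0][0, 0, 10]
    assert masks[1][0, 0, 10]


def test_non_ascending_edges_are_rejected():
    with pytest.raises(geo.GeometryError, match="ascending"):
        geo.shell_masks(np.zeros((2, 2, 2)), (0.0, 2.0, 1.0))


def test_shell_volumes_match_analytic_annulus(cylinder_labels):
    """Band voxel counts vs π((R+d2)² − (R+d1)²)·L within 2%."""
    lv = cylinder_labels
    dist = geo.distance_from_root(lv)
    masks = geo.shell_masks(dist, (0.0, 1.0, 2.0))
    nz = lv.shape[0]
    R = 500.0 / lv.voxel_size  # voxels
    per_mm = 1000.0 / lv.voxel_size
    for i, (d1, d2) in enumerate([(0.0, per_mm), (per_mm, 2 * per_mm)]):
        analytic = np.pi * ((R + d2) ** 2 - (R + d1) ** 2) * nz
        assert masks[i].sum() == pytest.approx(analytic, rel=0.02)


# ----------------------------------------------------------------- porosity
def test_porosity_extremes():
    labels = np.full((2, 2, 2), SOLID, dtype=np.uint8)
    labels[0, 0, 0] = ROOT
    lv = LabelVolume(data=labels, voxel_size=16.0)
    region = np.ones((2, 2, 2), dtype=bool)
    assert geo.porosity(region, lv) == 0.0
    lv_pore = LabelVolume(data=np.full((2, 2, 2), PORE, dtype=np.uint8), voxel_size=16.0)
    assert geo.porosity(region, lv_pore) == 100.0
    with pytest.raises(geo.GeometryError, match="non-root"):
        geo.porosity(np.array([[[True]]]), LabelVolume(data=np.full((1, 1, 1), ROOT, dtype=np.uint8), voxel_size=16.0))


def test_porosity_of_union_is_voxel_weighted_mean(rooted_phantom):
    _, _, truth = rooted_phantom
    dist = geo.distance_from_root(truth)
    m1, m2 = geo.shell_masks(dist, (0.0, 1.0, 2.0))
    p1, p2 = geo.porosity(m1, truth), geo.porosity(m2, truth)
    n1, n2 = m1.sum(), m2.sum()
    p_union = geo.porosity(m1 | m2, truth)
    assert p_union == pytest.approx((p1 * n1 + p2 * n2) / (n1 + n2), abs=1e-9)


def test_phantom_band_porosity_recovery(rooted_phantom):
    _, _, truth = rooted_phantom
    prof = geo.shell_profile(truth, (0.0, 1.0, 2.0, 3.0))
    assert prof.porosity_pct[0] == pytest.approx(28.0, abs=1.0)


# ------------------------------------------------------ rhizosheath boundary
def _profiles(elevated_hi_mm, n=4, seed0=40):
    profiles = []
    for rep in range(n):
        profile = [(0.0, float(h), 0.28) for h in [elevated_hi_mm] if h > 0]
        if elevated_hi_mm == 2.0:
            profile = [(0.0, 1.0, 0.28), (1.0, 2.0, 0.28)]
        spec = desk_phantom_spec(seed=seed0 + rep, porosity_profile=profile)
        _, truth = generate_phantom(spec)
        profiles.append(geo.shell_profile(truth, (0.0, 1.0, 2.0, 3.0), sample_id=f"r{rep}"))
    return profiles


def test_elevated_first_band_puts_boundary_at_1mm():
    det = geo.detect_rhizosheath(_profiles(1.0))
    assert det.boundary_mm == 1.0
    assert det.status == "ok"


def test_flat_profiles_detect_no_rhizosheath():
    det = geo.detect_rhizosheath(_profiles(0.0, seed0=50))
    assert det.boundary_mm == 0.0
    assert det.status == "no rhizosheath detected"


def test_two_band_elevation_puts_boundary_at_2mm():
    det = geo.detect_rhizosheath(_profiles(2.0, seed0=60))
    assert det.boundary_mm == 2.0


def test_detection_requires_three_replicates():
    with pytest.raises(geo.GeometryError, match=">= 3"):
        geo.detect_rhizosheath(_profiles(1.0, n=2, seed0=70))


# ------------------------------------------------------------ region masks
def test_extract_regions_match_shell_masks(rooted_phantom):
    _, _, truth = rooted_phantom
    dist = geo.distance_from_root(truth)
    rhizo, bulk = geo.extract_regions(truth, dist, 1.0)
    m1, m2 = geo.shell_masks(dist, (0.0, 1.0, 2.0))
    np.testing.assert_array_equal(rhizo, m1)
    np.testing.assert_array_equal(bulk, m2)
    assert not (rhizo & bulk).any()
    with pytest.raises(geo.GeometryError, match="boundary"):
        geo.extract_regions(truth, dist, 0.0)


def test_extracted_region_volumes_match_annulus(cylinder_labels):
    dist = geo.distance_from_root(cylinder_labels)
    rhizo, bulk = geo.extract_regions(cylinder_labels, dist, 1.0)
    nz = cylinder_labels.shape[0]
    R = 500.0 / cylinder_labels.voxel_size
    per_mm = 1000.0 / cylinder_labels.voxel_size
    assert rhizo.sum() == pytest.approx(np.pi * ((R + per_mm) ** 2 - R**2) * nz, rel=0.02)
    assert bulk.sum() == pytest.approx(np.pi * ((R + 2 * per_mm) ** 2 - (R + per_mm) ** 2) * nz, rel=0.02)


# ----------------------------------------------------------- unplanted core
def test_unplanted_slab_slice_arithmetic():
    lv = LabelVolume(data=np.zeros((400, 8, 8), dtype=np.uint8), voxel_size=16.0)
    core = geo.unplanted_core(lv)
    z_extent = np.flatnonzero(core.any(axis=(1, 2)))
    assert len(z_extent) == 62  # floor(1000/16)
    assert z_extent[0] == 400 // 2 - 62 // 2


def test_unplanted_core_porosity_matches_global(rooted_phantom):
    spec = desk_phantom_spec(seed=33, root_radius=0.0, porosity_profile=[])
    _, truth = generate_phantom(spec)
    core = geo.unplanted_core(truth)
    assert geo.porosity(core, truth) == pytest.approx(100 * (truth.data == PORE).mean(), abs=1.0)


def test_unplanted_core_refuses_rooted_volume(rooted_phantom):
    _, _, truth = rooted_phantom
    with pytest.raises(geo.GeometryError, match="without root"):
        geo.unplanted_core(truth)


def test_unplanted_core_refuses_thin_stack():
    lv = LabelVolume(data=np.zeros((10, 8, 8), dtype=np.uint8), voxel_size=16.0)
    with pytest.raises(geo.GeometryError, match="thinner"):
        geo.unplanted_core(lv)


# ------------------------------------------------------------- connectivity
def flood_fill_connectivity(mask: np.ndarray) -> float:
    """Independent BFS flood-fill Γ-indicator (26-neighbourhood)."""
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    visited = np.zeros_like(mask, dtype=bool)
    total = int(mask.sum())
    largest = 0
    coords = np.argwhere(mask)
    mask_set = mask
    for start in coords:
        start = tuple(start)
        if visited[start]:
            continue
        size = 0
        queue = collections.deque([start])
        visited[start] = True
        while queue:
            z, y, x = queue.popleft()
            size += 1
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (
                    0 <= p[0] < mask.shape[0]
                    and 0 <= p[1] < mask.shape[1]
                    and 0 <= p[2] < mask.shape[2]
                    and mask_set[p]
                    and not visited[p]
                ):
                    visited[p] = True
                    queue.append(p)
        largest = max(largest, size)
    return 100.0 * largest / total


def test_single_connected_network_is_100():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2] = True
    res = geo.pore_connectivity(mask, window=None)
    assert res.connectivity_pct == 100.0
    assert res.n_components == 1


def test_two_equal_clusters_give_50():
    mask = np.zeros((9, 3, 3), dtype=bool)
    mask[0:2] = True
    mask[6:8] = True
    res = geo.pore_connectivity(mask, window=None)
    assert res.connectivity_pct == 50.0
    assert res.n_components == 2


def test_random_mask_matches_flood_fill_oracle():
    rng = np.random.default_rng(7)
    mask = rng.random((64, 64, 64)) < 0.30
    res = geo.pore_connectivity(mask, window=None)
    assert res.connectivity_pct == pytest.approx(flood_fill_connectivity(mask), abs=1e-12)


def test_connectivity_invariant_to_translation_and_axis_permutation():
    rng = np.random.default_rng(8)
    mask = np.zeros((40, 40, 40), dtype=bool)
    mask[4:28, 4:28, 4:28] = rng.random((24, 24, 24)) < 0.3
    base = geo.pore_connectivity(mask, window=None).connectivity_pct
    shifted = np.roll(mask, (5, -3, 2), axis=(0, 1, 2))
    assert geo.pore_connectivity(shifted, window=None).connectivity_pct == base
    permuted = np.transpose(mask, (2, 0, 1))
    assert geo.pore_connectivity(permuted, window=None).connectivity_pct == base


def test_middle_100_slice_window():
    assert geo.middle_slices_window(400) == slice(150, 250)
    mask = np.zeros((400, 4, 4), dtype=bool)
    mask[0] = True  # outside the window
    mask[200] = True
    res = geo.pore_connectivity(mask, window="middle100")
    assert res.total_pore_voxels == 16


def test_no_pores_in_window_is_an_error():
    with pytest.raises(geo.GeometryError, match="no pore"):
        geo.pore_connectivity(np.zeros((4, 4, 4), dtype=bool), window=None)
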