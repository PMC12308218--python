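import numpy as np
import pytest

import myodens as md
from myodens.segmentation import SkinPeel, _prune_small
from myodens.volume import (ADIPOSE, BACKGROUND, BONE, INTRAMUSCULAR_FAT,
                            MUSCLE, SKIN, UNCLASSIFIED, CTVolume)

NO_FILTER = dict(gaussian_sigma=0.0)


def cube_volume(data, **kw):
    return CTVolume(np.asarray(data, dtype=np.float32), **kw)


# ---------------------------------------------------------------- preprocess

def test_preprocess_preserves_constants():
    vol = cube_volume(np.full((8, 8, 8), 37.0))
    out = md.preprocess(vol)
    assert np.allclose(out.data, 37.0, atol=1e-4)
    assert out.voxel_um == pytest.approx(2 * vol.voxel_um)
    assert (out.slope, out.intercept) == (vol.slope, vol.intercept)


def test_preprocess_block_mean_without_filter():
    data = np.zeros((2, 2, 2))
    data[1, :, :] = 100.0  # block {0 x4, 100 x4}
    out = md.preprocess(cube_volume(data), md.SegmentationConfig(**NO_FILTER))
    assert out.data.shape == (1, 1, 1)
    assert out.data[0, 0, 0] == pytest.approx(50.0)


def test_preprocess_checkerboard_averages_to_zero():
    idx = np.indices((6, 6, 6)).sum(axis=0)
    data = np.where(idx % 2 == 0, 100.0, -100.0)
    # independent oracle: brute-force block averaging
    oracle = np.zeros((3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                oracle[i, j, k] = data[2*i:2*i+2, 2*j:2*j+2, 2*k:2*k+2].mean()
    out = md.preprocess(cube_volume(data), md.SegmentationConfig(**NO_FILTER))
    assert np.allclose(out.data, oracle)
    assert np.allclose(out.data, 0.0)


def test_preprocess_pads_odd_shapes_by_replication():
    data = np.arange(5 * 4 * 4, dtype=float).reshape(5, 4, 4)
    out = md.preprocess(cube_volume(data), md.SegmentationConfig(**NO_FILTER))
    assert out.data.shape == (3, 2, 2)


# ------------------------------------------------------------ delineate_limb

def test_limb_mask_matches_analytic_cylinder(clean_phantom):
    spec, vol, truth = clean_phantom
    ds = md.preprocess(vol)
    mask = md.delineate_limb(ds)
    r = spec.limb_radius / 2.0  # downscaled voxels
    analytic = np.pi * r ** 2 * ds.shape[2]
    shell = 2 * np.pi * r * ds.shape[2]  # 1-voxel-thick boundary shell
    assert abs(mask.sum() - analytic) <= shell


def test_all_air_volume_is_rejected():
    vol = cube_volume(np.full((8, 8, 8), -1000.0))
    with pytest.raises(ValueError, match="no above-air"):
        md.delineate_limb(vol)


def test_two_disjoint_limbs_keep_only_larger():
    data = np.full((40, 20, 4), -1000.0)
    data[2:18, 4:16, :] = 50.0    # large block
    data[30:36, 8:12, :] = 50.0   # small block
    mask = md.delineate_limb(cube_volume(data))
    assert mask[10, 10, 2]
    assert not mask[32, 10, 2]


# ---------------------------------------------------------------- peel_skin

def brute_force_inplane_depth(mask):
    """Per-slice min Euclidean distance to a background pixel (oracle)."""
    depth = np.zeros(mask.shape)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        bg = np.argwhere(~sl)
        for (i, j) in np.argwhere(sl):
            depth[i, j, k] = np.sqrt(((bg - (i, j)) ** 2).sum(axis=1)).min()
    return depth


def test_peel_matches_distance_transform_oracle():
    x, y = np.indices((30, 30))
    disk = (x - 14.5) ** 2 + (y - 14.5) ** 2 < 12.0 ** 2
    mask = np.repeat(disk[:, :, None], 3, axis=2)
    cfg = md.SegmentationConfig(skin_thickness=5)
    peel = md.peel_skin(mask, cfg)
    depth = brute_force_inplane_depth(mask)
    assert np.array_equal(peel.skin, mask & (depth <= 5))
    assert np.array_equal(peel.interior, mask & (depth > 5))


def test_peel_is_a_partition(noisy_phantom):
    _, vol, _ = noisy_phantom
    ds = md.preprocess(vol)
    mask = md.delineate_limb(ds)
    peel = md.peel_skin(mask)
    assert not (peel.skin & peel.interior).any()
    assert np.array_equal(peel.skin | peel.interior, mask)
    assert not peel.degenerate


def test_thin_limb_flags_degenerate_interior():
    x, y = np.indices((20, 20))
    disk = (x - 9.5) ** 2 + (y - 9.5) ** 2 < 6.0 ** 2  # radius < skin thickness
    mask = np.repeat(disk[:, :, None], 2, axis=2)
    with pytest.warns(UserWarning, match="thinner"):
        peel = md.peel_skin(mask, md.SegmentationConfig(skin_thickness=20))
    assert peel.degenerate
    assert not peel.interior.any()


# -------------------------------------------------------------- exclude_bone

def test_bone_mask_equals_ground_truth_labels(clean_phantom):
    spec, vol, truth = clean_phantom
    # no filtering / downscaling so voxels stay pure tissue constants
    cfg = md.SegmentationConfig(gaussian_sigma=0.0, downscale_factor=1)
    interior = truth.labels != BACKGROUND
    bone = md.exclude_bone(vol, interior, cfg)
    assert np.array_equal(bone, truth.labels == BONE)


def test_empty_bone_mask_allowed():
    vol = cube_volume(np.full((4, 4, 4), 100.0))
    bone = md.exclude_bone(vol, np.ones((4, 4, 4), bool))
    assert not bone.any()


def test_calcification_blob_is_bone_not_muscle():
    data = np.full((10, 10, 10), 300.0)
    data[4:6, 4:6, 4:6] = 900.0  # small calcification inside muscle
    vol = cube_volume(data)
    region = np.ones(data.shape, bool)
    bone = md.exclude_bone(vol, region)
    labels = md.plant_seeds(vol, region & ~bone,
                            md.SegmentationConfig(min_seed_voxels=1))
    assert np.all(labels[bone] == BACKGROUND)  # excluded from soft tissue
    assert bone.sum() == 8


# --------------------------------------------------------------- plant_seeds

def test_seed_windows():
    data = np.full((6, 6, 6), 50.0)      # unclassified HU
    data[0] = 300.0                       # muscle window
    data[1] = -400.0                      # adipose window
    vol = cube_volume(data)
    labels = md.plant_seeds(vol, np.ones(data.shape, bool),
                            md.SegmentationConfig(min_seed_voxels=1))
    assert np.all(labels[0] == MUSCLE)
    assert np.all(labels[1] == ADIPOSE)
    assert np.all(labels[2:] == UNCLASSIFIED)


def test_seed_pruning_boundary_is_exclusive_at_50():
    m50 = np.zeros((20, 20, 4), bool)
    m50[1:6, 1:11, 1] = True          # 5 x 10 connected component: 50 voxels
    m49 = m50.copy()
    m49[1, 1, 1] = False              # drop one corner: 49 voxels
    assert not _prune_small(m49, 50, 3).any()      # 49 voxels: removed
    assert _prune_small(m50, 50, 3).sum() == 50    # exactly 50: retained


def test_no_seeds_at_zero_hu():
    vol = cube_volume(np.zeros((5, 5, 5)))
    labels = md.plant_seeds(vol, np.ones((5, 5, 5), bool))
    assert np.all(labels == UNCLASSIFIED)


# ----------------------------------------------------- iterate_classification

def brute_force_iterate(labels, hu, iterations, midpoint=-50.0):
    """Independent per-voxel neighbourhood-scan re-implementation."""
    labels = labels.copy()
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    nx, ny, nz = labels.shape
    for _ in range(iterations):
        new = labels.copy()
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if labels[i, j, k] != UNCLASSIFIED:
                        continue
                    near_m = near_a = False
                    for dx, dy, dz in offs:
                        x, y, z = i + dx, j + dy, k + dz
                        if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                            if labels[x, y, z] == MUSCLE:
                                near_m = True
                            elif labels[x, y, z] == ADIPOSE:
                                near_a = True
                    if near_m and near_a:
                        new[i, j, k] = MUSCLE if hu[i, j, k] >= midpoint else ADIPOSE
                    elif near_m:
                        new[i, j, k] = MUSCLE
                    elif near_a:
                        new[i, j, k] = ADIPOSE
        labels = new
    return labels


def test_octahedral_growth_of_single_seed():
    labels = np.full((9, 9, 9), UNCLASSIFIED, dtype=np.int8)
    labels[4, 4, 4] = MUSCLE
    vol = cube_volume(np.zeros((9, 9, 9)))
    out = md.iterate_classification(labels, vol, md.SegmentationConfig(iterations=2))
    assert (out == MUSCLE).sum() == 25  # centred octahedron, L1 radius 2


def test_zero_iterations_is_identity():
    rng = np.random.default_rng(0)
    labels = rng.choice([MUSCLE, ADIPOSE, UNCLASSIFIED, SKIN], size=(6, 6, 6)).astype(np.int8)
    vol = cube_volume(rng.normal(0, 100, (6, 6, 6)))
    out = md.iterate_classification(labels, vol, md.SegmentationConfig(iterations=0))
    assert np.array_equal(out, labels)


def test_contested_voxel_resolved_by_hu_proximity():
    # muscle seed at x=0 and adipose seed at x=4, three unclassified between:
    # round 1 claims x=1 (muscle) and x=3 (adipose); round 2 contests x=2.
    labels = np.full((5, 1, 1), UNCLASSIFIED, dtype=np.int8)
    labels[0] = MUSCLE
    labels[4] = ADIPOSE
    hu = np.zeros((5, 1, 1))
    hu[2] = 80.0  # >= -50 HU -> muscle
    out = md.iterate_classification(labels, cube_volume(hu),
                                    md.SegmentationConfig(iterations=2))
    assert out[2, 0, 0] == MUSCLE
    hu[2] = -120.0  # < -50 HU -> adipose
    out = md.iterate_classification(labels, cube_volume(hu),
                                    md.SegmentationConfig(iterations=2))
    assert out[2, 0, 0] == ADIPOSE


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dilation_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    shape = (12, 12, 12)
    labels = rng.choice([UNCLASSIFIED] * 6 + [MUSCLE, ADIPOSE, SKIN, BONE],
                        size=shape).astype(np.int8)
    hu = rng.normal(-50.0, 150.0, shape)
    vol = cube_volume(hu)
    for iters in (1, 3, 10):
        ours = md.iterate_classification(labels, vol,
                                         md.SegmentationConfig(iterations=iters))
        oracle = brute_force_iterate(labels, hu, iters)
        assert np.array_equal(ours, oracle)


def test_labels_grow_monotonically_and_partition_is_preserved():
    rng = np.random.default_rng(4)
    shape = (10, 10, 10)
    labels = rng.choice([UNCLASSIFIED] * 8 + [MUSCLE, ADIPOSE], size=shape).astype(np.int8)
    vol = cube_volume(rng.normal(0, 200, shape))
    prev = labels
    for k in range(1, 6):
        cur = md.iterate_classification(labels, vol, md.SegmentationConfig(iterations=k))
        assert np.all(cur[prev == MUSCLE] == MUSCLE)
        assert np.all(cur[prev == ADIPOSE] == ADIPOSE)
        assert ((cur == UNCLASSIFIED).sum() <= (prev == UNCLASSIFIED).sum())
        # only unclassified voxels ever change class
        changed = cur != prev
        assert np.all(prev[changed] == UNCLASSIFIED)
        prev = cur


# ------------------------------------------------------------ compute_outcomes

def test_all_muscle_soft_tissue_gives_full_fraction():
    labels = md.TissueLabelMap(np.full((4, 4, 4), MUSCLE, dtype=np.int8), voxel_um=121.4)
    vol = cube_volume(np.full((4, 4, 4), 300.0), voxel_um=121.4)
    out = md.compute_outcomes(vol, labels)
    assert out.mvtv_pct == pytest.approx(100.0)
    assert out.mv_cm3 == pytest.approx(out.tv_cm3)


def test_musd_is_affine_map_of_constant_hu():
    labels = md.TissueLabelMap(np.full((4, 4, 4), MUSCLE, dtype=np.int8), voxel_um=60.7)
    vol = cube_volume(np.full((4, 4, 4), 60.0), voxel_um=60.7, slope=0.4, intercept=0.0)
    out = md.compute_outcomes(vol, labels)
    assert out.musd == pytest.approx(24.0)


def test_zero_muscle_reports_missing_musd():
    labels = md.TissueLabelMap(np.full((4, 4, 4), ADIPOSE, dtype=np.int8), voxel_um=121.4)
    vol = cube_volume(np.full((4, 4, 4), -300.0), voxel_um=121.4)
    with pytest.warns(UserWarning, match="MusD undefined"):
        out = md.compute_outcomes(vol, labels)
    assert np.isnan(out.musd)


def test_musd_monotone_in_fat_fraction():
    musds = []
    for f in (0.0, 0.15, 0.3):
        spec = md.PhantomSpec(shape=(120, 120, 6), limb_radius=50.0,
                              skin_thickness=8.0, fat_thickness=14.0,
                              bone_radius=5.0, fat_fraction=f, noise_sd=0.0, seed=3)
        vol, truth = md.generate_phantom(spec)
        # density recomputed from ground-truth labels (oracle route)
        compartment = (truth.labels == MUSCLE) | (truth.labels == INTRAMUSCULAR_FAT)
        musds.append(vol.to_density(vol.data[compartment].mean()))
    assert musds[0] > musds[1] > musds[2]


# -------------------------------------------------------------------- segment

def test_segment_is_deterministic(noisy_phantom):
    _, vol, _ = noisy_phantom
    l1, o1 = md.segment(vol)
    l2, o2 = md.segment(vol)
    assert np.array_equal(l1.labels, l2.labels)
    assert (o1.musd, o1.mv_cm3, o1.tv_cm3, o1.mvtv_pct) == \
           (o2.musd, o2.mv_cm3, o2.tv_cm3, o2.mvtv_pct)


def test_segment_recovers_muscle_volume_within_5pct(noisy_phantom):
    _, vol, truth = noisy_phantom
    _, out = md.segment(vol)
    assert out.mv_cm3 == pytest.approx(truth.muscle_volume_cm3, rel=0.05)


def test_calibration_linearity(noisy_phantom):
    _, vol, _ = noisy_phantom
    _, out1 = md.segment(vol)
    vol2 = vol.with_data(vol.data, slope=2 * vol.slope, intercept=2 * vol.intercept + 5.0)
    _, out2 = md.segment(vol2)
    assert out2.musd == pytest.approx(2 * out1.musd + 5.0, rel=1e-6)
    assert out2.mv_cm3 == pytest.approx(out1.mv_cm3)
    assert out2.tv_cm3 == pytest.approx(out1.tv_cm3)
    assert out2.mvtv_pct == pytest.approx(out1.mvtv_pct)


def test_label_map_is_partition_of_grid(noisy_phantom):
    _, vol, _ = noisy_phantom
    labels, _ = md.segment(vol)
    codes = set(np.unique(labels.labels).tolist())
    assert codes <= {BACKGROUND, SKIN, BONE, MUSCLE, ADIPOSE, UNCLASSIFIED}
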