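"""Orientation/coherency analysis and per-cell marker quantification."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from invasig.imaging import (
    ImageScene,
    Segmentation,
    assign_position,
    border_alignment,
    compare_groups,
    nuc_cyt_ratio,
    region_quantify,
    segment_cells,
    structure_tensor,
)
from invasig.simulate import SceneSimConfig, make_stripes, simulate_invasion_scene

INTERIOR = (slice(24, -24),) * 2


class TestStructureTensor:
    @pytest.mark.parametrize("angle", [-75.0, -30.0, 0.0, 30.0, 60.0, 90.0])
    def test_stripe_orientation_recovered(self, angle):
        field = structure_tensor(make_stripes((200, 200), angle))
        med = np.median(field.theta_deg[INTERIOR])
        delta = abs(med - angle) % 180.0
        assert min(delta, 180.0 - delta) < 2.0
        assert np.median(field.coherency[INTERIOR]) > 0.95

    def test_rotation_shifts_orientation(self):
        # rotating the pattern by generating at angle + delta shifts the
        # median recovered orientation by delta
        base = np.median(structure_tensor(make_stripes((200, 200), 10.0)).theta_deg[INTERIOR])
        shifted = np.median(structure_tensor(make_stripes((200, 200), 35.0)).theta_deg[INTERIOR])
        assert shifted - base == pytest.approx(25.0, abs=2.0)

    def test_white_noise_is_incoherent(self):
        rng = np.random.default_rng(0)
        field = structure_tensor(rng.normal(size=(256, 256)), sigma_w=8.0)
        assert np.median(field.coherency[INTERIOR]) < 0.2

    def test_constant_image_zero_coherency(self):
        field = structure_tensor(np.full((64, 64), 3.0))
        assert np.all(field.coherency == 0.0)

    def test_coherency_invariant_to_affine_rescale(self):
        img = make_stripes((128, 128), 20.0)
        a = structure_tensor(img).coherency
        b = structure_tensor(5.0 * img + 100.0).coherency
        assert np.allclose(a[INTERIOR], b[INTERIOR], atol=1e-9)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            structure_tensor(np.zeros((4, 4, 4)))


def make_disk_scene(centers, nuc_val=200.0, cyt_val=100.0, shape=(200, 200),
                    rn=4, rc=7):
    """Scene with disk cells at given centers; returns scene and expected ratio."""
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]].astype(float)
    nuclear = np.full(shape, 10.0)
    marker = np.full(shape, cyt_val)
    for r0, c0 in centers:
        d = np.hypot(rr - r0, cc - c0)
        nuclear[d <= rn] = 200.0
        marker[d <= rn] = nuc_val
    return ImageScene(channels={"nuclear": nuclear, "marker": marker},
                      pixel_size=1.0)


class TestSegmentationAndRatios:
    def test_five_separated_nuclei(self):
        centers = [(30, 30), (30, 100), (100, 30), (100, 100), (150, 160)]
        seg = segment_cells(make_disk_scene(centers))
        assert seg.n_cells == 5

    def test_blank_image_zero_cells(self):
        scene = ImageScene(channels={"nuclear": np.zeros((64, 64))}, pixel_size=1.0)
        assert segment_cells(scene).n_cells == 0

    def test_provided_masks_pass_through(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[5:10, 5:10] = 1
        scene = ImageScene(channels={"marker": np.ones((32, 32))},
                           pixel_size=1.0, masks={"nuclei": labels})
        seg = segment_cells(scene)
        assert np.array_equal(seg.nuclei, labels)

    def test_ratio_closed_form(self):
        scene = make_disk_scene([(50, 50)], nuc_val=100.0)
        seg = segment_cells(scene)
        marker = np.where(seg.nuclei == 1, 100.0, 50.0)
        meas = nuc_cyt_ratio(seg, marker)
        assert len(meas) == 1
        assert meas[0].ratio == pytest.approx(2.0)

    def test_uniform_marker_ratio_one(self):
        scene = make_disk_scene([(50, 50), (120, 120)])
        seg = segment_cells(scene)
        meas = nuc_cyt_ratio(seg, np.full((200, 200), 7.0))
        assert all(m.ratio == pytest.approx(1.0) for m in meas)

    def test_ratio_invariant_to_marker_gain(self):
        scene, _ = simulate_invasion_scene(SceneSimConfig(seed=3))
        seg = segment_cells(scene)
        a = [m.ratio for m in nuc_cyt_ratio(seg, scene.channels["marker"])]
        b = [m.ratio for m in nuc_cyt_ratio(seg, 3.7 * scene.channels["marker"])]
        assert np.allclose(a, b)

    def test_planted_class_ratios_recovered(self, scene_default):
        scene, truth = scene_default
        seg = segment_cells(scene)
        meas = nuc_cyt_ratio(seg, scene.channels["marker"])
        meas = assign_position(seg, meas, scene.masks["organoid"])
        planted = truth.extras["ratios_by_class"]
        by_class = {}
        for m in meas:
            by_class.setdefault(m.position_class, []).append(m.ratio)
        for cls, vals in by_class.items():
            assert abs(np.mean(vals) / planted[cls] - 1.0) < 0.10


class TestPositionAssignment:
    def test_planted_classes_recovered(self, scene_default):
        scene, truth = scene_default
        seg = segment_cells(scene)
        meas = nuc_cyt_ratio(seg, scene.channels["marker"])
        meas = assign_position(seg, meas, scene.masks["organoid"])
        centers = truth.extras["centers"]
        carr = np.array([[c["row"], c["col"]] for c in centers])
        agree = total = 0
        for m in meas:
            d = np.hypot(carr[:, 0] - m.centroid[0], carr[:, 1] - m.centroid[1])
            j = int(d.argmin())
            if d[j] < 5:
                total += 1
                agree += centers[j]["class"] == m.position_class
        assert total >= 0.9 * len(centers)
        assert agree / total >= 0.90

    def test_detached_cell_is_single_and_center_is_core(self):
        centers = [(100, 100), (30, 170)]
        scene = make_disk_scene(centers)
        seg = segment_cells(scene)
        meas = nuc_cyt_ratio(seg, scene.channels["marker"])
        organoid = np.zeros((200, 200), dtype=bool)
        rr, cc = np.mgrid[0:200, 0:200]
        organoid[np.hypot(rr - 100, cc - 100) <= 60] = True
        meas = assign_position(seg, meas, organoid)
        classes = {tuple(np.round(m.centroid).astype(int)): m.position_class
                   for m in meas}
        assert classes[(100, 100)] == "core"
        assert classes[(30, 170)] == "single"

    def test_no_mask_derivable_all_single(self):
        scene = make_disk_scene([(30, 30)])
        seg = segment_cells(scene)
        meas = nuc_cyt_ratio(seg, scene.channels["marker"])
        # an explicit empty mask cannot be eroded into an interior
        meas = assign_position(seg, meas, np.zeros((200, 200), dtype=bool))
        assert all(m.position_class == "single" for m in meas)


class TestBorderAlignment:
    def test_perpendicular_stripes_all_bins_aligned(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[:, :100] = True  # border normal points along +x (0 degrees)
        field = structure_tensor(make_stripes((300, 300), 0.0))
        prof = border_alignment(field, mask, pixel_size=1.0, depth_um=100.0)
        assert prof.bins["aligned"].all()

    def test_parallel_stripes_not_counted(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[:, :100] = True
        field = structure_tensor(make_stripes((300, 300), 90.0))
        prof = border_alignment(field, mask, pixel_size=1.0, depth_um=60.0)
        # fibers parallel to the border deviate ~90 deg from the normal:
        # no perpendicular pixels, hence no aligned bin
        assert not prof.bins["aligned"].any()

    def test_isotropic_noise_below_cutoff(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((300, 300), dtype=bool)
        mask[:, :100] = True
        field = structure_tensor(rng.normal(size=(300, 300)), sigma_w=8.0)
        prof = border_alignment(field, mask, pixel_size=1.0, cutoff=0.2)
        assert not prof.bins["aligned"].any()

    def test_zero_depth_empty_profile(self):
        mask = np.ones((50, 50), dtype=bool)
        mask[40:, :] = False
        field = structure_tensor(np.zeros((50, 50)))
        prof = border_alignment(field, mask, pixel_size=1.0, depth_um=0.0)
        assert len(prof.bins) == 0

    def test_empty_mask_rejected(self):
        field = structure_tensor(np.zeros((50, 50)))
        with pytest.raises(ValueError):
            border_alignment(field, np.zeros((50, 50), dtype=bool), 1.0)


class TestRegionsAndStats:
    def _measurements(self, scene):
        seg = segment_cells(scene)
        return nuc_cyt_ratio(seg, scene.channels["marker"])

    def test_uniform_scene_equal_region_means(self):
        scene, _ = simulate_invasion_scene(
            SceneSimConfig(seed=2, nuc_cyt_ratio_by_class={
                "strand": 2.0, "core": 2.0, "single": 2.0})
        )
        meas = self._measurements(scene)
        zone = np.ones(scene.shape, dtype=bool)
        table = region_quantify(meas, zone, scene.pixel_size, n_regions=4,
                                region_size_um2=40_000, seed=1)
        means = table["mean_ratio"].dropna()
        assert means.std() < 0.05 * means.mean()

    def test_zone_smaller_than_region_is_error(self):
        zone = np.zeros((100, 100), dtype=bool)
        zone[:40, :40] = True
        with pytest.raises(ValueError, match="max feasible"):
            region_quantify([], zone, pixel_size=1.0, n_regions=1,
                            region_size_um2=62_500)

    def test_mann_whitney_exact_example(self):
        stat, p = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert p == pytest.approx(1.0)

    def test_kruskal_identical_three_groups(self):
        stat, p = compare_groups(
            {"a": [1.0, 2], "b": [1.0, 2], "c": [1.0, 2]}, test="kruskal_wallis"
        )
        assert stat == pytest.approx(0.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0]})
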