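"""Threshold resolution, segmentation, and the volume battery."""

import numpy as np
import pytest

from petvol import (
    CubeROI,
    EllipsoidVOI,
    GeometryError,
    ReferenceStats,
    ThresholdSpec,
    default_battery,
    delineate,
    lesion_suvmax,
    load_battery,
    resolve_threshold,
    roi_stats,
    run_battery,
    save_battery,
    voi_for_lesion,
)

from conftest import make_image


class TestRoiStats:
    def test_uniform_region(self):
        img = make_image(np.full((11, 11, 11), 1.5), spacing=(2, 2, 2))
        stats = roi_stats(img, CubeROI(center=(10, 10, 10), side=10.0), "bone_marrow")
        assert stats.suv_mean == 1.5
        assert stats.suv_max == 1.5

    def test_two_voxel_roi_mean_and_max(self):
        vals = np.full((4, 1, 1), 9.0)
        vals[0, 0, 0], vals[1, 0, 0] = 1.0, 3.0
        img = make_image(vals)
        stats = roi_stats(img, CubeROI(center=(0.5, 0.0, 0.0), side=1.0), "parotid")
        assert stats.suv_mean == 2.0
        assert stats.suv_max == 3.0

    def test_blur_free_phantom_roi_recovers_manifest_truth(self, noiseless_cohort):
        _, scenes = noiseless_cohort
        scene = scenes[0]
        for tissue in scene.manifest.tissues:
            stats = roi_stats(
                scene.image, CubeROI(center=tissue.roi_center_mm, side=10.0), tissue.tissue
            )
            assert stats.suv_mean == pytest.approx(tissue.true_suvmean, abs=1e-12)

    def test_out_of_image_roi_raises(self):
        img = make_image(np.zeros((4, 4, 4)) + 1.0)
        with pytest.raises(GeometryError):
            roi_stats(img, CubeROI(center=(99, 99, 99), side=2.0), "pituitary")


class TestLesionSuvmax:
    def test_plateau_lesion_without_blur(self, noiseless_cohort):
        _, scenes = noiseless_cohort
        scene = scenes[0]
        lesion = scene.manifest.lesions[0]
        assert lesion_suvmax(scene.image, voi_for_lesion(lesion)) == lesion.plateau_suv

    def test_blur_lowers_suvmax_below_plateau(self, default_cohort):
        _, scenes = default_cohort
        for scene in scenes[:5]:
            lesion = scene.manifest.lesions[0]
            suvmax = lesion_suvmax(scene.image, voi_for_lesion(lesion))
            assert suvmax < lesion.plateau_suv
            # oracle: the max over the blurred image near the lesion
            assert suvmax == pytest.approx(
                scene.image.values[scene.labels.mask(lesion.label)].max()
            )

    def test_empty_after_exclusion_raises(self):
        img = make_image(np.ones((5, 5, 5)))
        voi = EllipsoidVOI(
            center=(2, 2, 2),
            semi_axes=(1.5, 1.5, 1.5),
            exclusions=(CubeROI(center=(2, 2, 2), side=20.0),),
        )
        with pytest.raises(GeometryError):
            lesion_suvmax(img, voi)


def _ref(tissue, mean, maxv=None):
    return ReferenceStats(
        tissue=tissue, suv_mean=mean, suv_max=maxv or mean, roi=CubeROI(center=(0, 0, 0))
    )


class TestResolveThreshold:
    def test_all_four_families(self):
        refs = {"bone_marrow": _ref("bone_marrow", 1.4), "pituitary": _ref("pituitary", 10.0)}
        assert resolve_threshold(ThresholdSpec("fixed", 4.0)) == 4.0
        assert resolve_threshold(
            ThresholdSpec("isocontour", 45.0), lesion_suv_max=20.0
        ) == pytest.approx(9.0)
        assert resolve_threshold(
            ThresholdSpec("ref_multiplicative", 150.0, "bone_marrow"), refs=refs
        ) == pytest.approx(2.1)
        assert resolve_threshold(
            ThresholdSpec("ref_subtractive", 70.0, "pituitary"), refs=refs
        ) == pytest.approx(3.0)

    def test_subtractive_threshold_decreases_as_percent_grows(self):
        refs = {"pituitary": _ref("pituitary", 10.0)}
        resolved = [
            resolve_threshold(ThresholdSpec("ref_subtractive", v, "pituitary"), refs=refs)
            for v in (30, 40, 50, 60, 70, 80)
        ]
        assert all(a > b for a, b in zip(resolved, resolved[1:]))

    def test_missing_inputs_raise(self):
        with pytest.raises(ValueError, match="reference"):
            resolve_threshold(ThresholdSpec("ref_multiplicative", 150.0, "parotid"), refs={})
        with pytest.raises(ValueError, match="SUVmax"):
            resolve_threshold(ThresholdSpec("isocontour", 45.0))

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError):
            ThresholdSpec("fixed", -1.0)
        with pytest.raises(ValueError):
            ThresholdSpec("isocontour", 120.0)
        with pytest.raises(ValueError):
            ThresholdSpec("ref_subtractive", 100.0, "parotid")
        with pytest.raises(ValueError):
            ThresholdSpec("ref_multiplicative", 150.0)  # missing tissue
        with pytest.raises(ValueError):
            ThresholdSpec("fixed", 4.0, ref_tissue="parotid")


class TestDelineate:
    def test_uniform_voi_all_or_nothing(self):
        img = make_image(np.full((15, 15, 15), 5.0))
        voi = EllipsoidVOI(center=(7, 7, 7), semi_axes=(5, 5, 5))
        whole = delineate(img, voi, 4.0)
        n_voi = sum(
            (i - 7) ** 2 + (j - 7) ** 2 + (k - 7) ** 2 <= 25
            for i in range(15)
            for j in range(15)
            for k in range(15)
        )
        assert whole.mask.sum() == n_voi > 0
        empty = delineate(img, voi, 6.0)
        assert empty.volume_mL == 0.0
        assert not empty.mask.any()

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            img = make_image(rng.uniform(0, 10, (16, 16, 16)))
            voi = EllipsoidVOI(center=(7.5, 7.5, 7.5), semi_axes=(6, 5, 7))
            voi_mask = np.zeros(img.shape, dtype=bool)
            for i in range(16):
                for j in range(16):
                    for k in range(16):
                        q = ((i - 7.5) / 6) ** 2 + ((j - 7.5) / 5) ** 2 + ((k - 7.5) / 7) ** 2
                        voi_mask[i, j, k] = q <= 1
            for t in rng.uniform(0, 10, 4):
                res = delineate(img, voi, t)
                brute = voi_mask & np.array(
                    [v >= t for v in img.values.ravel()]
                ).reshape(img.shape)
                assert np.array_equal(res.mask, brute)

    def test_volume_non_increasing_in_threshold(self, default_cohort):
        _, scenes = default_cohort
        for scene in scenes[:4]:
            lesion = scene.manifest.lesions[0]
            voi = voi_for_lesion(lesion)
            vols = [delineate(scene.image, voi, t).volume_mL for t in np.linspace(0.1, 12, 50)]
            assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_exclusion_never_increases_volume(self, default_cohort):
        _, scenes = default_cohort
        scene = scenes[0]
        lesion = scene.manifest.lesions[0]
        voi = voi_for_lesion(lesion)
        excl = CubeROI(center=lesion.center_mm, side=6.0)
        voi_excl = EllipsoidVOI(center=voi.center, semi_axes=voi.semi_axes, exclusions=(excl,))
        for t in (0.6, 2.0, 4.0):
            assert (
                delineate(scene.image, voi_excl, t).volume_mL
                <= delineate(scene.image, voi, t).volume_mL
            )

    def test_largest_component_mode_drops_satellites(self):
        vals = np.full((21, 21, 21), 0.1)
        vals[8:13, 8:13, 8:13] = 5.0  # main blob
        vals[3, 3, 3] = 5.0  # disconnected satellite (inside the VOI)
        img = make_image(vals)
        voi = EllipsoidVOI(center=(10, 10, 10), semi_axes=(15, 15, 15))
        keep_all = delineate(img, voi, 4.0)
        largest = delineate(img, voi, 4.0, largest_component_only=True)
        assert keep_all.mask.sum() == 126
        assert largest.mask.sum() == 125


class TestRunBattery:
    def test_fixed_battery_volumes_non_increasing(self, default_cohort):
        _, scenes = default_cohort
        specs = [ThresholdSpec("fixed", v) for v in (2.5, 3.0, 3.5, 3.75, 4.0, 4.5, 5.0, 10.0, 15.0)]
        rows = run_battery(
            scenes[0].image, scenes[0].labels, scenes[0].manifest, specs
        )
        assert len(rows) == 1
        vols = [rows[0][s.label] for s in specs]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_empty_battery_keeps_identity_columns(self, default_cohort):
        _, scenes = default_cohort
        rows = run_battery(scenes[0].image, scenes[0].labels, scenes[0].manifest, [])
        row = rows[0]
        assert {"scene_id", "lesion_id", "ct_volume_mL", "lesion_suv_max"} <= set(row)

    def test_duplicate_specs_give_identical_columns(self, default_cohort):
        _, scenes = default_cohort
        a = ThresholdSpec("fixed", 4.0, label="a")
        b = ThresholdSpec("fixed", 4.0, label="b")
        row = run_battery(scenes[0].image, scenes[0].labels, scenes[0].manifest, [a, b])[0]
        assert row["a"] == row["b"]

    def test_noiseless_battery_reproduces_label_volume(self, noiseless_cohort):
        _, scenes = noiseless_cohort
        spec = ThresholdSpec("fixed", 4.0)
        row = run_battery(
            scenes[0].image, scenes[0].labels, scenes[0].manifest, [spec], truth="voxel"
        )[0]
        assert row[spec.label] == row["ct_volume_mL"]


class TestDefaultBattery:
    def test_reproduces_all_tabulated_rules(self):
        battery = default_battery()
        by_family = {}
        for s in battery:
            by_family.setdefault(s.family, []).append(s)
        assert len(by_family["fixed"]) == 9
        assert len(by_family["isocontour"]) == 9
        assert len(by_family["ref_multiplicative"]) == 13  # 5 BM + 7 parotid + 1 pituitary
        assert len(by_family["ref_subtractive"]) == 16  # 5 BM + 4 parotid + 7 pituitary
        labels = [s.label for s in battery]
        assert len(labels) == len(set(labels)) == 47

    def test_json_round_trip(self, tmp_path):
        battery = default_battery()
        path = tmp_path / "battery.json"
        save_battery(path, battery)
        assert load_battery(path) == battery
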