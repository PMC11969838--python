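"""Segmentation, shape descriptors, GLCM texture and classical classifiers."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from causalcyto.exceptions import ConfigurationError, SegmentationError
from causalcyto.morphometrics import (
    FEATURE_COLUMNS,
    GLCMConfig,
    SegmentationMasks,
    classical_classify,
    compute_shape_features,
    compute_texture_features,
    extract_cell_features,
    segment_cell,
)
from causalcyto.synthetic import generate_cell_image


def disk_mask(radius, side=None, center=None):
    side = side or (2 * radius + 11)
    center = center or (side // 2, side // 2)
    mask = np.zeros((side, side), dtype=bool)
    rr, cc = draw_disk(center, radius, shape=mask.shape)
    mask[rr, cc] = True
    return mask


def concentric_cell(r_nuc=8, r_cyt=20, side=51):
    cyt = disk_mask(r_cyt, side)
    nuc = disk_mask(r_nuc, side)
    return SegmentationMasks(nuc, cyt & ~nuc, "ground_truth")


class TestShapeFeatures:
    def test_disk_matches_analytic_circle(self):
        masks = concentric_cell()
        # nucleus is a digital disk of radius 8
        f = compute_shape_features(masks)
        assert f.nucleus_area == pytest.approx(np.pi * 8**2, rel=0.05)
        assert f.nucleus_roundness == pytest.approx(1.0, abs=0.06)
        assert f.nucleus_elongation == pytest.approx(1.0, abs=0.06)

    def test_disk_radius_20_analytics(self):
        mask = disk_mask(20)
        cyt = disk_mask(24, side=mask.shape[0])
        f = compute_shape_features(SegmentationMasks(mask, cyt & ~mask, "gt"))
        assert f.nucleus_area == pytest.approx(np.pi * 400, rel=0.02)
        assert f.nucleus_roundness == pytest.approx(1.0, abs=0.03)
        assert f.nucleus_elongation == pytest.approx(1.0, abs=0.03)

    def test_ellipse_elongation_near_axis_ratio(self):
        mask = np.zeros((81, 81), dtype=bool)
        rr, cc = draw_ellipse(40, 40, 10, 30)
        mask[rr, cc] = True
        cyt = disk_mask(36, side=81)
        f = compute_shape_features(SegmentationMasks(mask, cyt & ~mask, "gt"))
        assert f.nucleus_elongation == pytest.approx(1 / 3, rel=0.07)

    def test_concentric_nucleus_position_is_one(self):
        f = compute_shape_features(concentric_cell())
        assert f.nucleus_position >= 0.98

    def test_offset_nucleus_scores_lower(self):
        side = 51
        cyt = disk_mask(20, side)
        nuc = disk_mask(6, side, center=(25, 36))
        f = compute_shape_features(SegmentationMasks(nuc, cyt & ~nuc, "gt"))
        assert f.nucleus_position < 0.8

    def test_nc_ratio_monotone_in_nucleus_area(self):
        side = 61
        cyt = disk_mask(25, side)
        prev = 0.0
        for r in (5, 8, 12, 16):
            nuc = disk_mask(r, side)
            f = compute_shape_features(SegmentationMasks(nuc, cyt & ~nuc, "gt"))
            assert f.nc_ratio > prev
            prev = f.nc_ratio

    def test_translation_and_rotation_invariance_for_disks(self):
        side = 71
        base = compute_shape_features(
            SegmentationMasks(
                disk_mask(9, side, (30, 30)),
                disk_mask(22, side, (33, 33)) & ~disk_mask(9, side, (30, 30)),
                "gt",
            )
        )
        moved = compute_shape_features(
            SegmentationMasks(
                disk_mask(9, side, (38, 36)),
                disk_mask(22, side, (41, 39)) & ~disk_mask(9, side, (38, 36)),
                "gt",
            )
        )
        assert moved.nucleus_area == base.nucleus_area
        assert moved.nucleus_roundness == pytest.approx(
            base.nucleus_roundness, rel=0.03
        )

    def test_shortest_never_exceeds_longest(self):
        for label in (1, 3, 5):
            rec = generate_cell_image(label, seed=7)
            f = compute_shape_features(
                SegmentationMasks(rec.nucleus_mask, rec.cytoplasm_mask, "gt")
            )
            assert f.nucleus_shortest_diameter <= f.nucleus_longest_diameter
            assert 0 < f.nucleus_elongation <= 1
            assert 0 < f.nc_ratio < 1


class TestTextureFeatures:
    def test_constant_image_conventions(self):
        img = np.full((16, 16), 0.5)
        t = compute_texture_features(img)
        assert t.contrast == 0.0
        assert t.energy == 1.0
        assert t.homogeneity == 1.0
        assert t.correlation == 1.0

    def test_checkerboard_matches_hand_built_cooccurrence(self):
        # 2-level checkerboard: horizontally adjacent pixels always differ.
        board = np.indices((8, 8)).sum(axis=0) % 2
        img = board * (7.5 / 8)  # quantizes to levels {0, 7}
        cfg = GLCMConfig(levels=8, distance=1, angles=(0.0,))
        t = compute_texture_features(img, config=cfg)
        # hand-built 2x2 GLCM over levels {0,7}: all mass off-diagonal,
        # contrast = (7-0)^2 = 49
        assert t.contrast == pytest.approx(49.0)
        assert t.energy == pytest.approx(np.sqrt(0.5))
        assert t.homogeneity == pytest.approx(1 / 8)
        assert t.correlation == pytest.approx(-1.0)

    def test_matches_skimage_on_full_frame(self, rng):
        from skimage.feature import graycomatrix, graycoprops

        img = rng.random((24, 24))
        q = np.clip((img * 8).astype(int), 0, 7)
        ref = graycomatrix(q, [1], [0], levels=8, symmetric=True, normed=True)
        cfg = GLCMConfig(levels=8, distance=1, angles=(0.0,))
        t = compute_texture_features(img, config=cfg)
        assert t.contrast == pytest.approx(
            float(graycoprops(ref, "contrast")[0, 0]), rel=1e-10
        )
        # homogeneity here is the inverse-difference form 1/(1+|i-j|)
        # (skimage's property of that name uses 1/(1+(i-j)^2))
        i, j = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        expected_hom = float(np.sum(ref[:, :, 0, 0] / (1 + np.abs(i - j))))
        assert t.homogeneity == pytest.approx(expected_hom, rel=1e-10)
        assert t.correlation == pytest.approx(
            float(graycoprops(ref, "correlation")[0, 0]), abs=1e-10
        )

    def test_bounds_on_random_images(self, rng):
        for _ in range(10):
            t = compute_texture_features(rng.random((12, 12)))
            assert 0 < t.energy <= 1
            assert 0 < t.homogeneity <= 1
            assert t.contrast >= 0
            assert -1 <= t.correlation <= 1


class TestSegmentation:
    def test_synthetic_cells_reach_dice_090(self):
        dices = []
        for s in range(15):
            label = s % 5 + 1
            rec = generate_cell_image(label, seed=400 + s)
            seg = segment_cell(rec.image)
            inter = (seg.nucleus_mask & rec.nucleus_mask).sum()
            dices.append(
                2 * inter / (seg.nucleus_mask.sum() + rec.nucleus_mask.sum())
            )
        assert np.mean(dices) >= 0.90

    def test_blank_image_fails_loudly(self):
        with pytest.raises(SegmentationError):
            segment_cell(np.full((32, 32, 3), 0.7))

    def test_ground_truth_bypass_keeps_masks(self):
        rec = generate_cell_image(2, seed=1)
        masks = SegmentationMasks(
            rec.nucleus_mask, rec.cytoplasm_mask, provenance="ground_truth"
        )
        row = extract_cell_features(rec.image, masks)
        assert masks.provenance == "ground_truth"
        assert list(row) == FEATURE_COLUMNS


class TestClassicalClassify:
    @staticmethod
    def planted_table(rng, n=200):
        import pandas as pd

        y = rng.integers(1, 4, size=n)
        signal = y + rng.normal(0, 0.4, size=n)
        signal2 = -y + rng.normal(0, 0.6, size=n)
        noise = rng.normal(size=(n, 6))
        df = pd.DataFrame(
            np.column_stack([signal, signal2, noise]),
            columns=["s1", "s2"] + [f"n{i}" for i in range(6)],
        )
        return df, y

    def test_separable_feature_reaches_perfect_accuracy(self, rng):
        import pandas as pd

        y = np.repeat([1, 2], 60)
        df = pd.DataFrame({"f": y * 10.0})
        for kind in ("KNN", "SVM", "RF"):
            report, _ = classical_classify(df, y, model_kind=kind, seed=0)
            assert report.accuracy == 1.0

    def test_deterministic_given_seed(self, rng):
        df, y = self.planted_table(rng)
        a, _ = classical_classify(df, y, "RF", seed=4)
        b, _ = classical_classify(df, y, "RF", seed=4)
        assert a.to_json() == b.to_json()

    def test_unknown_model_rejected(self, rng):
        df, y = self.planted_table(rng)
        with pytest.raises(ConfigurationError):
            classical_classify(df, y, model_kind="MLP")

    def test_causal_selection_drops_noise_keeps_signal(self, rng):
        df, y = self.planted_table(rng, n=250)
        report, factor_set = classical_classify(
            df, y, "SVM", use_causal_selection=True, seed=0
        )
        assert "s1" in factor_set.kept
        assert len(factor_set.kept) <= 5  # most noise columns removed

    def test_selection_ignores_test_labels(self, rng):
        """Shuffling labels of the held-out rows must not change selection."""
        df, y = self.planted_table(rng, n=250)
        _, fs1 = classical_classify(df, y, "KNN", use_causal_selection=True, seed=3)
        y2 = y.copy()
        # rebuild the internal test mask the same way classical_classify does
        r = np.random.default_rng(3)
        test_mask = np.zeros(y.size, dtype=bool)
        for c in np.unique(y):
            members = r.permutation(np.flatnonzero(y == c))
            test_mask[members[: max(1, int(round(0.25 * members.size)))]] = True
        y2[test_mask] = np.random.default_rng(99).permutation(y2[test_mask])
        _, fs2 = classical_classify(df, y2, "KNN", use_causal_selection=True, seed=3)
        assert sorted(fs1.kept) == sorted(fs2.kept)
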