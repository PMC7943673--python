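"""Threshold segmentation, contour algebra and segmentation QA statistics."""

import numpy as np
import pytest

from sirtdose import (
    ContourMask,
    ContourSet,
    dice,
    interoperator_rms_cv,
    normal_liver,
    registration_qa,
    threshold_contour,
)
from sirtdose.errors import ContourError, ParameterError

from conftest import counts_volume, make_mask, sphere_mask


class TestThresholdContour:
    def test_uniform_counts_select_whole_voi(self, grid16):
        voi = sphere_mask(grid16, (8, 8, 8), 6, label="voi")
        counts = counts_volume(grid16, np.full(grid16.shape, 3.7))
        mask = threshold_contour(counts, voi)
        assert np.array_equal(mask.values, voi.values)

    def test_scale_invariance(self, grid16, rng):
        voi = sphere_mask(grid16, (8, 8, 8), 6, label="voi")
        vals = rng.random(grid16.shape)
        m1 = threshold_contour(counts_volume(grid16, vals), voi)
        m2 = threshold_contour(counts_volume(grid16, vals * 7.3), voi)
        assert np.array_equal(m1.values, m2.values)

    def test_monotone_in_fraction(self, grid16, rng):
        voi = sphere_mask(grid16, (8, 8, 8), 7, label="voi")
        counts = counts_volume(grid16, rng.random(grid16.shape))
        lo = threshold_contour(counts, voi, fraction=0.10)
        hi = threshold_contour(counts, voi, fraction=0.50)
        assert np.all(hi.values <= lo.values)  # larger fraction => subset

    def test_voi_local_maximum(self, grid16):
        # a hot spot outside the VOI must not distort the threshold
        voi = sphere_mask(grid16, (8, 8, 8), 4, label="voi")
        vals = np.ones(grid16.shape)
        vals[0, 0, 0] = 1e6  # extrahepatic hot voxel
        mask = threshold_contour(counts_volume(grid16, vals), voi)
        assert mask.n_voxels == voi.n_voxels

    def test_empty_voi_rejected(self, grid16):
        empty = make_mask(grid16, np.zeros(grid16.shape, bool))
        with pytest.raises(ContourError):
            threshold_contour(counts_volume(grid16, np.ones(grid16.shape)), empty)

    def test_all_zero_counts_warn_and_empty(self, grid16):
        voi = sphere_mask(grid16, (8, 8, 8), 5, label="voi")
        with pytest.warns(UserWarning, match="zero"):
            mask = threshold_contour(counts_volume(grid16, np.zeros(grid16.shape)), voi)
        assert mask.n_voxels == 0

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1])
    def test_bad_fraction(self, grid16, fraction):
        voi = sphere_mask(grid16, (8, 8, 8), 5)
        with pytest.raises(ParameterError):
            threshold_contour(counts_volume(grid16, np.ones(grid16.shape)), voi,
                              fraction=fraction)


class TestNormalLiver:
    def test_empty_tumor_gives_whole_liver(self, grid16):
        liver = sphere_mask(grid16, (8, 8, 8), 6, label="liver")
        empty = make_mask(grid16, np.zeros(grid16.shape, bool), label="tumor")
        nl = normal_liver(liver, empty)
        assert np.array_equal(nl.values, liver.values)

    def test_tumor_equals_liver_gives_empty(self, grid16):
        liver = sphere_mask(grid16, (8, 8, 8), 6, label="liver")
        nl = normal_liver(liver, liver)
        assert nl.n_voxels == 0

    def test_volume_partition(self, grid16):
        liver = sphere_mask(grid16, (8, 8, 8), 6, label="liver")
        tumor = sphere_mask(grid16, (8, 8, 8), 3, label="tumor")
        nl = normal_liver(liver, tumor)
        assert liver.volume_ml == pytest.approx(tumor.volume_ml + nl.volume_ml)

    def test_volume_arithmetic_in_ml(self):
        # forced arithmetic on a literal grid: 2000 mL liver, 203 mL tumor
        from sirtdose import VoxelGrid

        grid = VoxelGrid((2203, 1, 1), (10.0, 10.0, 10.0))  # 1 mL voxels
        vals = np.zeros(grid.shape, dtype=np.uint8)
        vals[:2000] = 1
        liver = ContourMask(grid, vals, label="liver")
        tvals = np.zeros(grid.shape, dtype=np.uint8)
        tvals[:203] = 1
        tumor = ContourMask(grid, tvals, label="tumor")
        nl = normal_liver(liver, tumor)
        assert nl.volume_ml == pytest.approx(1797.0)

    def test_outside_tumor_clipped_with_warning(self, grid16):
        liver = sphere_mask(grid16, (8, 8, 8), 4, label="liver")
        tumor = sphere_mask(grid16, (12, 8, 8), 3, label="tumor")
        with pytest.warns(UserWarning, match="outside"):
            nl = normal_liver(liver, tumor)
        assert not np.any(nl.values & tumor.values)
        with pytest.raises(ContourError):
            normal_liver(liver, tumor, on_outside="error")


class TestContourSet:
    def test_partition_invariants_enforced(self, grid16):
        liver = sphere_mask(grid16, (8, 8, 8), 6, label="liver")
        tumor = sphere_mask(grid16, (8, 8, 8), 3, label="tumor")
        cs = ContourSet.from_liver_tumor(liver, tumor)
        assert not np.any(cs.tumor.values & cs.normal.values)
        assert np.array_equal(cs.tumor.values | cs.normal.values, cs.liver.values)

    def test_rejects_inconsistent_normal(self, grid16):
        liver = sphere_mask(grid16, (8, 8, 8), 6, label="liver")
        tumor = sphere_mask(grid16, (8, 8, 8), 3, label="tumor")
        with pytest.raises(ContourError):
            ContourSet(liver, tumor, liver)  # "normal" overlapping tumor


class TestDice:
    def test_identical_nonempty_is_one(self, grid16):
        m = sphere_mask(grid16, (8, 8, 8), 5)
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self, grid16):
        a = sphere_mask(grid16, (4, 4, 4), 2)
        b = sphere_mask(grid16, (12, 12, 12), 2)
        assert dice(a, b) == 0.0

    def test_hand_computed_overlap(self):
        from sirtdose import VoxelGrid

        grid = VoxelGrid((120, 1, 1), (1.0, 1.0, 1.0))
        a = np.zeros(grid.shape, np.uint8)
        b = np.zeros(grid.shape, np.uint8)
        a[:100] = 1          # |a| = 100
        b[20:120] = 1        # |b| = 100, overlap 80
        assert dice(ContourMask(grid, a), ContourMask(grid, b)) == pytest.approx(0.80)

    def test_symmetry(self, grid16, rng):
        a = make_mask(grid16, rng.random(grid16.shape) > 0.5)
        b = make_mask(grid16, rng.random(grid16.shape) > 0.5)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_rejected(self, grid16):
        e = make_mask(grid16, np.zeros(grid16.shape, bool))
        with pytest.raises(ContourError):
            dice(e, e)


class TestRegistrationQA:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.93, True), (0.85, True), (0.70, False), (1.0, True)],
    )
    def test_threshold_inclusive(self, value, expected):
        assert registration_qa(value) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            registration_qa(1.2)


class TestInterOperatorRmsCv:
    def test_identical_pairs_zero(self):
        assert interoperator_rms_cv([(100, 100), (55, 55)]) == 0.0

    def test_single_pair_hand_value(self):
        # sd(95,105) = 7.0711 (n-1), mean 100 -> CV 7.07%
        assert interoperator_rms_cv([(95, 105)]) == pytest.approx(7.0711, abs=1e-3)

    def test_two_value_shortcut_formula(self, rng):
        va, vb = 80.0, 120.0
        expected = abs(va - vb) / (np.sqrt(2) * np.mean([va, vb])) * 100
        assert interoperator_rms_cv([(va, vb)]) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ParameterError):
            interoperator_rms_cv([(100, 0)])
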