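import itertools

import numpy as np
import pytest

from motion4d.errors import DegenerateRoiError
from motion4d.organ_motion import (
    compute_means,
    direction_means,
    euclidean,
    euclidean_consistency,
    load_displacements,
    load_printed_means,
    mean_consistency,
    modality_difference_table,
    roi_translation,
)
from motion4d.phantom import Grid, PhantomSpec, render_phantom


@pytest.fixture(scope="module")
def per_patient():
    return load_displacements()


@pytest.fixture(scope="module")
def printed_means():
    return load_printed_means()


class TestEuclidean:
    @pytest.mark.parametrize(
        "dx,dy,dz,expected",
        [
            (4.1, 9.2, 7.0, 12.3),
            (7.7, 9.0, 9.7, 15.3),
            (0.0, 0.0, 0.0, 0.0),
            (1.1, 3.1, 2.7, 4.3),
        ],
    )
    def test_per_patient_norms(self, dx, dy, dz, expected):
        assert euclidean(dx, dy, dz) == expected

    def test_component_permutation_invariance(self):
        for perm in itertools.permutations((4.1, 9.2, 7.0)):
            assert euclidean(*perm) == 12.3

    def test_monotone_in_each_component(self):
        base = euclidean(2.0, 3.0, 4.0)
        assert euclidean(2.5, 3.0, 4.0) >= base
        assert euclidean(2.0, 3.0, 4.5) >= base

    def test_sign_invariance(self):
        assert euclidean(-4.1, 9.2, -7.0) == 12.3


class TestDirectionMeans:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((4.1, 1.1), 2.6),
            ((5.5, 1.0, 4.4), 3.6),
            ((3.0,), 3.0),
            ((7.0, 2.7), 4.9),  # 4.85 rounds up, unlike binary-float rounding
            ((7.7, 0.4), 4.1),  # 4.05 rounds up
        ],
    )
    def test_half_up_means(self, values, expected):
        assert direction_means(values) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_means([])


class TestTableRebuild:
    def test_modality_difference_table_matches_published_cells(self, printed_means):
        diffs = modality_difference_table(printed_means).set_index(["organ", "comparison"])
        liver_ax = diffs.loc[("liver", "CT-AX_MR")]
        assert (liver_ax["dx"], liver_ax["dy"], liver_ax["dz"], liver_ax["euclidean"]) == (
            -0.3,
            -4.0,
            3.4,
            0.7,
        )
        liver_cor = diffs.loc[("liver", "CT-COR_MR")]
        assert (liver_cor["dx"], liver_cor["dy"], liver_cor["dz"], liver_cor["euclidean"]) == (
            -1.8,
            -3.5,
            2.3,
            -0.4,
        )
        kid_ax = diffs.loc[("kidney_mean", "CT-AX_MR")]
        assert (kid_ax["dx"], kid_ax["dy"], kid_ax["dz"], kid_ax["euclidean"]) == (
            0.6,
            -0.6,
            -2.0,
            -1.5,
        )
        kid_cor = diffs.loc[("kidney_mean", "CT-COR_MR")]
        assert (kid_cor["dx"], kid_cor["dy"], kid_cor["dz"], kid_cor["euclidean"]) == (
            0.5,
            -0.7,
            -2.7,
            -2.2,
        )

    def test_modality_minus_itself_is_zero(self, printed_means):
        doubled = printed_means.copy()
        doubled.loc[doubled["modality"] == "AX_MR", ["dx", "dy", "dz", "euclidean"]] = (
            doubled.loc[doubled["modality"] == "CT", ["dx", "dy", "dz", "euclidean"]].to_numpy()
        )
        diffs = modality_difference_table(doubled)
        ax_rows = diffs[diffs["comparison"] == "CT-AX_MR"]
        assert (ax_rows[["dx", "dy", "dz", "euclidean"]].to_numpy() == 0).all()

    def test_consistent_mean_cells_reproduced(self, per_patient, printed_means):
        flags = mean_consistency(per_patient, printed_means)
        consistent = flags[flags["consistent"]]
        # every cell that is arithmetically consistent matches exactly
        assert (consistent["printed"] == consistent["computed_from_printed_inputs"]).all()
        # e.g. the liver axial column reproduces fully
        liver_ax = flags[(flags["organ"] == "liver") & (flags["modality"] == "AX_MR")]
        assert liver_ax["consistent"].all()

    def test_known_inconsistent_cells_flagged_not_matched(self, per_patient, printed_means):
        flags = mean_consistency(per_patient, printed_means).set_index(
            ["organ", "modality", "direction"]
        )
        # published means that imply unrounded sources are flagged
        assert not flags.loc[("kidney_mean", "AX_MR", "euclidean"), "consistent"]  # 6.1 vs 6.2
        assert not flags.loc[("kidney_mean", "COR_MR", "euclidean"), "consistent"]  # 6.8 vs 6.9
        assert not flags.loc[("liver", "CT", "dy"), "consistent"]
        n_flagged = int((~flags["consistent"]).sum())
        assert n_flagged == 10

    def test_per_patient_euclidean_flags(self, per_patient):
        flags = euclidean_consistency(per_patient).set_index(["organ", "modality", "patient_id"])
        assert not flags.loc[("liver", "CT", 1), "consistent"]  # 17.4 printed vs 17.5 computed
        assert not flags.loc[("liver", "COR_MR", 2), "consistent"]
        assert flags["consistent"].sum() == len(flags) - 2

    def test_compute_means_shape(self, per_patient):
        means = compute_means(per_patient)
        assert set(means["modality"]) == {"CT", "AX_MR", "COR_MR"}
        assert len(means) == 6


@pytest.fixture(scope="module")
def grid():
    return Grid((48, 48, 48), (1.5, 1.5, 1.5), ("LR", "AP", "SI"))


class TestRoiTranslation:
    def test_identical_volumes_give_zero(self, grid):
        vol = render_phantom(0.0, PhantomSpec(), grid)
        roi = (slice(12, 36), slice(12, 36), slice(12, 36))
        dx, dy, dz = roi_translation(vol, vol, roi, grid.voxel)
        assert (dx, dy, dz) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_subvoxel_shift_recovered(self):
        # 7.5 mm is 3.75 voxels on a 2 mm grid: a genuine sub-voxel case
        grid = Grid((40, 40, 40), (2.0, 2.0, 2.0), ("LR", "AP", "SI"))
        spec = PhantomSpec()
        exhale = render_phantom(0.0, spec, grid)
        inhale = render_phantom(7.5, spec, grid)
        roi = (slice(8, 32), slice(8, 32), slice(12, 36))
        dx, dy, dz = roi_translation(inhale, exhale, roi, grid.voxel)
        assert abs(dx) < 0.25 and abs(dy) < 0.25
        assert dz == pytest.approx(7.5, abs=0.25)

    def test_integer_shift_exact(self, grid):
        spec = PhantomSpec()
        exhale = render_phantom(0.0, spec, grid)
        inhale = np.roll(exhale, 2, axis=2)  # exactly two voxels
        # ROI wide enough that the sphere stays fully inside every candidate
        # window, so the correlation peak is exact and symmetric
        roi = (slice(8, 40), slice(8, 40), slice(10, 42))
        dx, dy, dz = roi_translation(inhale, exhale, roi, grid.voxel, max_shift_vox=5)
        assert dz == pytest.approx(2 * 1.5, abs=1e-9)

    def test_flat_roi_rejected(self, grid):
        vol = np.ones(grid.shape)
        with pytest.raises(DegenerateRoiError):
            roi_translation(vol, vol, (slice(0, 8), slice(0, 8), slice(0, 8)))
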