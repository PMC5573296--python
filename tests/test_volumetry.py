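"""Region volumetry: voxel counting, masking, lobe totals, asymmetry, paired tests."""

import numpy as np
import pytest

from atlaskit import (
    AlignmentError,
    DomainError,
    LabelVolume,
    TissueMask,
    asymmetry_pct,
    gm_masked_volume,
    lobe_total,
    paired_lr_test,
    percent_of_lobe,
    region_volume,
)
from atlaskit.cohort_tables import load_reference_volume_stats

from conftest import make_block_volume


class TestRegionVolume:
    def test_unit_voxel_block(self):
        vol = make_block_volume(code=84, voxel_mm=1.0)
        assert region_volume(vol, 84) == 1000.0

    def test_scanner_voxel_block(self):
        vol = make_block_volume(code=84, voxel_mm=0.9375)
        assert region_volume(vol, 84) == pytest.approx(1000 * 0.9375**3)
        assert region_volume(vol, 84) == pytest.approx(823.9746, abs=1e-3)

    def test_unknown_code_rejected(self):
        with pytest.raises(DomainError):
            region_volume(make_block_volume(), 99)

    def test_absent_region_returns_zero(self, caplog):
        vol = make_block_volume(code=84)
        with caplog.at_level("WARNING"):
            assert region_volume(vol, 32) == 0.0
        assert "zero voxels" in caplog.text

    def test_volume_conservation(self, tiny_cohort):
        """Region volumes plus background account for the whole grid volume."""
        labels, _, _ = tiny_cohort
        vol = labels[0]
        total = vol.grid.size * vol.voxel_volume
        regions = sum(region_volume(vol, c) for c in vol.codes())
        background = (vol.grid == 0).sum() * vol.voxel_volume
        assert regions + background == pytest.approx(total)

    def test_matches_generator_bookkeeping(self, tiny_cohort):
        labels, _, truth = tiny_cohort
        for sid, vol in zip(truth.subject_ids, labels):
            for code, count in truth.voxel_counts[sid].items():
                assert region_volume(vol, code) == pytest.approx(count * vol.voxel_volume)


class TestGmMaskedVolume:
    def test_identity_mask(self):
        vol = make_block_volume(code=84)
        mask = TissueMask(grid=np.ones(vol.grid.shape, dtype=np.uint8), affine=vol.affine)
        assert gm_masked_volume(vol, mask, 84) == region_volume(vol, 84)

    def test_zero_mask(self):
        vol = make_block_volume(code=84)
        mask = TissueMask(grid=np.zeros(vol.grid.shape, dtype=np.uint8), affine=vol.affine)
        assert gm_masked_volume(vol, mask, 84) == 0.0

    def test_half_mask(self):
        vol = make_block_volume(code=84)
        half = np.zeros(vol.grid.shape, dtype=np.uint8)
        half[:10] = 1  # block spans slices 5..14 -> exactly half covered
        mask = TissueMask(grid=half, affine=vol.affine)
        assert gm_masked_volume(vol, mask, 84) == region_volume(vol, 84) / 2

    def test_monotone_under_masking(self, tiny_cohort):
        labels, masks, _ = tiny_cohort
        for vol, mask in zip(labels, masks):
            for code in vol.codes():
                assert gm_masked_volume(vol, mask, code) <= region_volume(vol, code)

    def test_shape_mismatch(self):
        vol = make_block_volume()
        mask = TissueMask(grid=np.ones((5, 5, 5), dtype=np.uint8))
        with pytest.raises(AlignmentError):
            gm_masked_volume(vol, mask, 84)


class TestLobeTotals:
    def test_published_native_left_means(self):
        vols = {84: 28085, 32: 16109, 60: 31405, 62: 46008}
        assert lobe_total(vols, "L") == 121607

    def test_published_mni_left_means(self):
        vols = {84: 36194, 32: 20805, 60: 41071, 62: 58793}
        assert lobe_total(vols, "L") == 156863

    def test_from_packaged_volume_stats(self):
        df = load_reference_volume_stats()
        sel = df[(df.space == "native") & (df.tissue == "GMWM") & (df.side == "L")]
        by_name = dict(zip(sel.region, sel.mean_mm3))
        vols = {84: by_name["SMG"], 32: by_name["AG"], 60: by_name["postCG"], 62: by_name["supPL"]}
        assert lobe_total(vols, "L") == 121607

    def test_zero_inputs(self):
        assert lobe_total({84: 0, 32: 0, 60: 0, 62: 0}, "L") == 0

    def test_missing_region(self):
        with pytest.raises(DomainError, match="missing"):
            lobe_total({84: 1.0}, "L")


class TestRatios:
    @pytest.mark.parametrize(
        "region,lobe,expected", [(28085, 121607, 23), (46008, 121607, 38), (5, 5, 100)]
    )
    def test_percent_of_lobe(self, region, lobe, expected):
        assert percent_of_lobe(region, lobe) == expected

    def test_percent_of_lobe_domain(self):
        with pytest.raises(DomainError):
            percent_of_lobe(1.0, 0.0)

    @pytest.mark.parametrize(
        "a,b,expected", [(36194, 33053, 9.5), (18172, 16628, 9.3), (7.0, 7.0, 0.0)]
    )
    def test_asymmetry(self, a, b, expected):
        assert asymmetry_pct(a, b) == expected

    def test_asymmetry_domain(self):
        with pytest.raises(DomainError):
            asymmetry_pct(1.0, 0.0)


class TestPairedTest:
    def test_identical_vectors(self):
        res = paired_lr_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_offset_is_exact(self):
        res = paired_lr_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(res.t) and res.t > 0 and res.p == 0.0

    def test_matches_closed_form(self):
        # classical paired t computed by hand: t = mean(d) / (sd(d)/sqrt(n))
        left = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        right = np.array([9.0, 11.5, 9.5, 12.0, 10.0])
        d = left - right
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = paired_lr_test(left, right)
        assert res.t == pytest.approx(expected_t)
        assert 0 < res.p < 1

    def test_smg_interhemispheric_difference_significant(self, reference_cohort):
        """Left SMG (grey+white) is significantly larger than right at p < 0.05."""
        left = reference_cohort.hemi_frame("L")["smg_gmwm"]
        right = reference_cohort.hemi_frame("R")["smg_gmwm"]
        res = paired_lr_test(left, right)
        assert res.significant_05 and res.t > 0
        assert not res.significant_01

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            paired_lr_test([1.0, 2.0], [1.0])


class TestNiftiIO:
    def test_label_volume_round_trip(self, tmp_path):
        vol = make_block_volume(code=84, voxel_mm=2.0)
        path = vol.to_nifti(tmp_path / "labels.nii.gz")
        back = LabelVolume.from_nifti(path)
        assert (back.grid == vol.grid).all()
        assert np.allclose(back.affine, vol.affine)
        assert back.voxel_volume == pytest.approx(8.0)

    def test_mask_round_trip(self, tmp_path):
        mask = TissueMask(grid=np.ones((4, 4, 4), dtype=np.uint8), affine=np.eye(4))
        path = mask.to_nifti(tmp_path / "mask.nii.gz")
        back = TissueMask.from_nifti(path)
        assert (back.grid == mask.grid).all()
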