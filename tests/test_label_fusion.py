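"""Label propagation, vote fusion, overlap metrics, leave-one-out evaluation."""

import math

import numpy as np
import pytest

from atlaskit import (
    AlignmentError,
    DomainError,
    IdentityProvider,
    LabelVolume,
    OracleProvider,
    TargetGrid,
    dice_from_jaccard,
    jaccard,
    leave_one_out,
    propagate_labels,
    vote_fusion,
    volume_error_pct,
)
from atlaskit.label_fusion import identity_transform

from conftest import make_block_volume


def _vol(grid, affine=None, space="common"):
    return LabelVolume(grid=np.asarray(grid, dtype=np.int32),
                       affine=affine if affine is not None else np.eye(4), space=space)


class TestPropagate:
    def test_identity_transform_preserves_labels(self):
        vol = make_block_volume(code=84, space="common")
        target = TargetGrid.of(vol)
        out = propagate_labels(vol, identity_transform(target), target)
        assert (out.grid == vol.grid).all()

    def test_whole_voxel_translation_preserves_volume(self):
        """A source shifted by a whole voxel in world space lands shifted, same size."""
        vol = make_block_volume(code=84, shape=(20, 20, 20), block=(slice(5, 15),) * 3)
        shifted_affine = vol.affine.copy()
        shifted_affine[0, 3] += 3.0  # source sits 3 mm further along x
        src = LabelVolume(grid=vol.grid, affine=shifted_affine, space="common")
        target = TargetGrid.of(vol)
        out = propagate_labels(src, identity_transform(target), target)
        assert (out.grid == 84).sum() == (vol.grid == 84).sum()
        assert (out.grid[8:18, 5:15, 5:15] == 84).all()

    def test_oracle_warp_roundtrip_is_near_identity(self, tiny_cohort, tiny_config):
        """Propagating a subject onto itself through the generator's exact warp
        and its inverse reproduces the labels up to a thin boundary shell."""
        labels, _, truth = tiny_cohort
        sid = truth.subject_ids[0]
        grid = TargetGrid.of(labels[0])
        op = OracleProvider(truth, grid)(sid, sid)
        out = op(labels[0])
        for code in labels[0].codes():
            assert jaccard(out, labels[0], code) > 0.9


class TestVoteFusion:
    def test_identical_inputs_fuse_to_themselves(self):
        vol = make_block_volume(code=84, space="common")
        fused = vote_fusion([vol, vol, vol])
        assert (fused.grid == vol.grid).all()

    def test_strict_majority(self):
        a = _vol([[[84]]]); b = _vol([[[84]]]); c = _vol([[[0]]])
        assert vote_fusion([a, b, c]).grid[0, 0, 0] == 84

    def test_tie_breaks_to_lowest_code(self):
        a = _vol([[[84]]]); b = _vol([[[32]]])
        assert vote_fusion([a, b]).grid[0, 0, 0] == 32

    def test_output_codes_subset_of_inputs(self, tiny_cohort):
        labels, _, _ = tiny_cohort
        fused = vote_fusion(labels)
        in_codes = set().union(*(set(v.codes()) for v in labels)) | {0}
        assert set(np.unique(fused.grid)).issubset(in_codes)

    def test_grid_mismatch(self):
        a = _vol(np.zeros((2, 2, 2)))
        b = _vol(np.zeros((3, 3, 3)))
        with pytest.raises(AlignmentError):
            vote_fusion([a, b])


class TestOverlapMetrics:
    def test_jaccard_identical(self):
        vol = make_block_volume(code=84)
        assert jaccard(vol, vol, 84) == 1.0

    def test_jaccard_disjoint(self):
        a = make_block_volume(code=84, block=(slice(0, 5),) * 3)
        b = make_block_volume(code=84, block=(slice(10, 15),) * 3)
        assert jaccard(a, b, 84) == 0.0

    def test_jaccard_half_overlapping_cubes(self):
        # two equal cubes overlapping in half their volume: J = (V/2)/(3V/2) = 1/3
        a = make_block_volume(code=84, block=(slice(0, 10), slice(0, 10), slice(0, 10)))
        b = make_block_volume(code=84, block=(slice(5, 15), slice(0, 10), slice(0, 10)))
        assert jaccard(a, b, 84) == pytest.approx(1 / 3)

    def test_jaccard_both_empty_is_missing(self):
        a = make_block_volume(code=84)
        assert math.isnan(jaccard(a, a, 32))

    @pytest.mark.parametrize("j,expected", [(0.69, 0.82), (1.0, 1.0), (0.0, 0.0)])
    def test_dice_from_jaccard(self, j, expected):
        assert round(dice_from_jaccard(j), 2) == expected

    def test_dice_bounds(self):
        with pytest.raises(DomainError):
            dice_from_jaccard(1.2)

    def test_dice_dominates_jaccard(self):
        for j in np.linspace(0.01, 0.99, 20):
            assert dice_from_jaccard(j) > j

    @pytest.mark.parametrize("auto,ref,expected", [(110, 100, 10.0), (100, 100, 0.0), (90, 100, -10.0)])
    def test_volume_error(self, auto, ref, expected):
        assert volume_error_pct(auto, ref) == expected

    def test_volume_error_domain(self):
        with pytest.raises(DomainError):
            volume_error_pct(1.0, 0.0)

    def test_mean_of_errors_differs_from_error_of_means(self):
        # per-pair errors averaged are the reported statistic, not error of totals
        autos = np.array([150.0, 80.0, 100.0])
        refs = np.array([100.0, 100.0, 200.0])
        per_pair = np.mean([volume_error_pct(a, r) for a, r in zip(autos, refs)])
        of_means = volume_error_pct(autos.mean(), refs.mean())
        assert per_pair == pytest.approx((50 - 20 - 50) / 3)
        assert per_pair != pytest.approx(of_means)


class TestLeaveOneOut:
    def test_identical_cohort_identity_provider_is_perfect(self):
        vol = make_block_volume(code=84, space="common")
        cohort = [(f"s{i}", vol) for i in range(3)]
        report = leave_one_out(cohort, IdentityProvider(TargetGrid.of(vol)), regions=[84])
        row = report.regions[0]
        assert row.jaccard_mean == 1.0
        assert row.jaccard_sd == 0.0
        assert row.volume_error_mean_pct == 0.0

    def test_needs_three_subjects(self):
        vol = make_block_volume(code=84, space="common")
        with pytest.raises(DomainError):
            leave_one_out([("a", vol), ("b", vol)], IdentityProvider(TargetGrid.of(vol)))

    def test_oracle_beats_identity(self, tiny_cohort):
        """Overlap improves monotonically with registration quality."""
        labels, _, truth = tiny_cohort
        cohort = list(zip(truth.subject_ids, labels))
        grid = TargetGrid.of(labels[0])
        rep_oracle = leave_one_out(cohort, OracleProvider(truth, grid))
        rep_identity = leave_one_out(cohort, IdentityProvider(grid))
        assert rep_oracle.mean_jaccard() > rep_identity.mean_jaccard()

    def test_fused_volumes_bias_toward_the_cohort_mean(self, syn_cohort):
        """With unregistered (identity) propagation, fusion overestimates small
        regions and underestimates large ones: the signed volume error falls
        with (reference volume - cohort mean volume)."""
        import scipy.stats

        labels, _, truth = syn_cohort
        cohort = list(zip(truth.subject_ids, labels))
        report = leave_one_out(cohort, IdentityProvider(TargetGrid.of(labels[0])))
        deviations, errors = [], []
        vox = labels[0].voxel_volume
        for code, entries in report.per_target.items():
            refs = {sid: truth.voxel_counts[sid][code] * vox for sid in entries}
            mean_ref = np.mean(list(refs.values()))
            for sid, metrics in entries.items():
                deviations.append(refs[sid] - mean_ref)
                errors.append(metrics["volume_error_pct"])
        rho = scipy.stats.spearmanr(deviations, errors).statistic
        assert rho < -0.5

    def test_report_frame_columns(self, tiny_cohort):
        labels, _, truth = tiny_cohort
        cohort = list(zip(truth.subject_ids, labels))
        report = leave_one_out(cohort, IdentityProvider(TargetGrid.of(labels[0])))
        df = report.to_frame()
        assert list(df.columns) == [
            "code", "region", "side", "manual_volume", "automatic_volume",
            "jaccard", "jaccard_sd", "jaccard_cv_pct", "volume_error_pct", "n",
        ]
        assert len(df) == 8
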