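"""Multi-atlas label propagation, majority-vote fusion and overlap evaluation.

Registration is strictly external: a :class:`TransformProvider` maps a
(source, target) subject pair to a resampling operator that carries the
source's label raster onto the target grid with nearest-neighbour semantics
(labels are categorical). Bundled providers cover the identity transform,
the synthetic generator's known ground-truth warps, and precomputed
deformation fields stored as NIfTI vector images.

The leave-one-out evaluation treats each subject in turn as the unlabelled
target, propagates every other subject's labels onto it, fuses them by
per-voxel majority vote, and scores the fused labels against the target's
own reference labels by Jaccard overlap and signed volume error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage, stats

from .morphometry import DomainError
from .regions import PARIETAL_REGIONS
from .volumetry import AlignmentError, LabelVolume, region_volume

log = logging.getLogger(__name__)

#: A resampling operator: carries a source LabelVolume onto a fixed target grid.
ResamplingOperator = Callable[[LabelVolume], LabelVolume]


class TransformProvider(Protocol):
    """Maps (source_id, target_id) to a resampling operator for that pair."""

    def __call__(self, source_id: str, target_id: str) -> ResamplingOperator: ...


@dataclass(frozen=True)
class TargetGrid:
    """Geometry of the grid labels are propagated onto."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def world_coords(self) -> np.ndarray:
        """(3, N) world coordinates of all voxel centres."""
        idx = np.indices(self.shape).reshape(3, -1)
        homog = np.vstack([idx, np.ones((1, idx.shape[1]))])
        return (np.asarray(self.affine) @ homog)[:3]

    @classmethod
    def of(cls, vol: LabelVolume) -> "TargetGrid":
        return cls(shape=tuple(vol.grid.shape), affine=np.asarray(vol.affine))


def resample_world_points(source: LabelVolume, world_pts: np.ndarray) -> np.ndarray:
    """Nearest-neighbour sample of a label raster at (3, N) world points.

    Points outside the source grid read background (0).
    """
    inv = np.linalg.inv(source.affine)
    vox = (inv[:3, :3] @ world_pts) + inv[:3, 3:4]
    return ndimage.map_coordinates(source.grid, vox, order=0, mode="constant", cval=0)


def identity_transform(target: TargetGrid) -> ResamplingOperator:
    """Resample a source volume onto the target grid with no spatial change."""

    def op(source: LabelVolume) -> LabelVolume:
        if source.grid.shape == target.shape and np.allclose(source.affine, target.affine):
            return LabelVolume(grid=source.grid.copy(), affine=target.affine.copy(), space=source.space)
        labels = resample_world_points(source, target.world_coords())
        return LabelVolume(
            grid=labels.reshape(target.shape).astype(np.int32),
            affine=target.affine.copy(),
            space=source.space,
        )

    return op


class IdentityProvider:
    """Provider returning the identity (unregistered) transform for every pair."""

    def __init__(self, target: TargetGrid):
        self._target = target

    def __call__(self, source_id: str, target_id: str) -> ResamplingOperator:
        return identity_transform(self._target)


class OracleProvider:
    """Provider using the synthetic generator's exact ground-truth warps.

    ``truth`` must expose ``subject_to_template(subject_id, world_pts)`` and
    ``template_to_subject(subject_id, template_pts)`` (the generator's
    forward/backward world-coordinate maps).
    """

    def __init__(self, truth, target: TargetGrid):
        self._truth = truth
        self._target = target
        self._tmpl_cache: dict[str, np.ndarray] = {}

    def _target_template_coords(self, target_id: str) -> np.ndarray:
        if target_id not in self._tmpl_cache:
            self._tmpl_cache.clear()  # one target at a time is enough
            pts = self._target.world_coords()
            self._tmpl_cache[target_id] = self._truth.subject_to_template(target_id, pts)
        return self._tmpl_cache[target_id]

    def __call__(self, source_id: str, target_id: str) -> ResamplingOperator:
        truth, target = self._truth, self._target

        def op(source: LabelVolume) -> LabelVolume:
            tmpl = self._target_template_coords(target_id)
            src_world = truth.template_to_subject(source_id, tmpl)
            labels = resample_world_points(source, src_world)
            return LabelVolume(
                grid=labels.reshape(target.shape).astype(np.int32),
                affine=target.affine.copy(),
                space=source.space,
            )

        return op


class PrecomputedFieldProvider:
    """Provider reading dense displacement fields from NIfTI vector images.

    Expects files ``<source>_to_<target>.nii.gz`` in ``field_dir``, each a
    4D (x, y, z, 3) image on the *target* grid whose vector at a target
    voxel displaces its world coordinate into the source's world space
    (pull-back convention).
    """

    def __init__(self, field_dir: str | Path, target: TargetGrid):
        self._dir = Path(field_dir)
        self._target = target

    def __call__(self, source_id: str, target_id: str) -> ResamplingOperator:
        path = self._dir / f"{source_id}_to_{target_id}.nii.gz"
        if not path.exists():
            path = path.with_suffix("").with_suffix(".nii")
        if not path.exists():
            raise FileNotFoundError(f"no displacement field for pair {source_id}->{target_id}")
        img = nib.load(str(path))
        field = np.asanyarray(img.dataobj).astype(float)
        target = self._target
        if field.shape != (*target.shape, 3):
            raise AlignmentError(
                f"field shape {field.shape} does not match target grid {(*target.shape, 3)}"
            )

        def op(source: LabelVolume) -> LabelVolume:
            pts = target.world_coords() + field.reshape(-1, 3).T
            labels = resample_world_points(source, pts)
            return LabelVolume(
                grid=labels.reshape(target.shape).astype(np.int32),
                affine=target.affine.copy(),
                space=source.space,
            )

        return op


def propagate_labels(
    atlas: LabelVolume, transform: ResamplingOperator, target: TargetGrid
) -> LabelVolume:
    """Carry an atlas's labels onto the target grid through a resampling operator."""
    out = transform(atlas)
    if out.grid.shape != target.shape or not np.allclose(out.affine, target.affine):
        raise AlignmentError("resampled volume does not lie on the target grid")
    return out


def vote_fusion(candidates: Sequence[LabelVolume]) -> LabelVolume:
    """Per-voxel majority vote over candidate label volumes.

    Ties are broken toward the lowest code (a documented convention; the
    standard per-voxel vote leaves ties open). Fusing n copies of one volume
    returns that volume.
    """
    if len(candidates) == 0:
        raise DomainError("need at least one candidate")
    ref = candidates[0]
    for c in candidates[1:]:
        if c.grid.shape != ref.grid.shape or not np.allclose(c.affine, ref.affine):
            raise AlignmentError("candidates are not on one grid")
    if len(candidates) == 1:
        return LabelVolume(grid=ref.grid.copy(), affine=ref.affine.copy(), space=ref.space)
    stack = np.stack([c.grid for c in candidates])
    # scipy's mode returns the smallest modal value, i.e. the lowest-code tie-break
    fused = stats.mode(stack, axis=0, keepdims=False).mode
    return LabelVolume(grid=fused.astype(np.int32), affine=ref.affine.copy(), space=ref.space)


def jaccard(a: LabelVolume, b: LabelVolume, code: int) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of one region's voxel sets.

    NaN (missing) when the region is absent from both volumes.
    """
    if a.grid.shape != b.grid.shape:
        raise AlignmentError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    in_a = a.grid == code
    in_b = b.grid == code
    union = int((in_a | in_b).sum())
    if union == 0:
        return float("nan")
    return int((in_a & in_b).sum()) / union


def dice_from_jaccard(j: float) -> float:
    """Convert a Jaccard index to the equivalent Dice index, 2J/(1+J)."""
    if not 0 <= j <= 1:
        raise DomainError(f"Jaccard index must be in [0, 1], got {j}")
    return 2.0 * j / (1.0 + j)


def volume_error_pct(auto_mm3: float, ref_mm3: float) -> float:
    """Signed percent volume error of an automatic vs reference volume."""
    if ref_mm3 <= 0:
        raise DomainError(f"reference volume must be > 0, got {ref_mm3}")
    return 100.0 * (auto_mm3 - ref_mm3) / ref_mm3


@dataclass(frozen=True)
class FusionRegionResult:
    """Leave-one-out metrics for one region (one row of the evaluation table)."""

    code: int
    name: str
    side: str
    mean_manual_mm3: float
    mean_auto_mm3: float
    jaccard_mean: float
    jaccard_sd: float
    jaccard_cv_pct: float
    volume_error_mean_pct: float
    n: int


@dataclass
class FusionReport:
    """Per-region leave-one-out metrics plus the per-target raw values."""

    regions: list[FusionRegionResult]
    per_target: "dict[int, dict[str, dict[str, float]]]"  # code -> target_id -> metrics

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "code": r.code,
                    "region": r.name,
                    "side": r.side,
                    "manual_volume": r.mean_manual_mm3,
                    "automatic_volume": r.mean_auto_mm3,
                    "jaccard": r.jaccard_mean,
                    "jaccard_sd": r.jaccard_sd,
                    "jaccard_cv_pct": r.jaccard_cv_pct,
                    "volume_error_pct": r.volume_error_mean_pct,
                    "n": r.n,
                }
                for r in self.regions
            ]
        )

    def mean_jaccard(self) -> float:
        return float(np.mean([r.jaccard_mean for r in self.regions]))


def leave_one_out(
    cohort: Sequence[tuple[str, LabelVolume]],
    provider: TransformProvider,
    regions: Sequence[int] | None = None,
) -> FusionReport:
    """Leave-one-out multi-atlas propagation with majority-vote fusion.

    Each subject serves once as target; all remaining subjects' labels are
    propagated onto its grid via the provider's transforms and fused by
    majority vote. Per region the mean/SD/CV% of the Jaccard index and the
    mean signed volume error (computed per pair, then averaged) are reported.
    """
    if len(cohort) < 3:
        raise DomainError(f"need at least 3 subjects, got {len(cohort)}")
    ids = [sid for sid, _ in cohort]
    if len(set(ids)) != len(ids):
        raise DomainError("duplicate subject ids in cohort")
    codes = sorted(regions) if regions is not None else sorted(PARIETAL_REGIONS)

    per_target: dict[int, dict[str, dict[str, float]]] = {c: {} for c in codes}
    manual: dict[int, list[float]] = {c: [] for c in codes}
    auto: dict[int, list[float]] = {c: [] for c in codes}

    for tgt_id, tgt_vol in cohort:
        target = TargetGrid.of(tgt_vol)
        candidates = []
        for src_id, src_vol in cohort:
            if src_id == tgt_id:
                continue
            try:
                op = provider(src_id, tgt_id)
                candidates.append(propagate_labels(src_vol, op, target))
            except Exception:  # provider failure: skip the pair, keep going
                log.exception("provider failed for pair %s->%s; pair skipped", src_id, tgt_id)
        if not candidates:
            log.warning("no usable sources for target %s; target skipped", tgt_id)
            continue
        fused = vote_fusion(candidates)
        for code in codes:
            ref_mm3 = region_volume(tgt_vol, code, dictionary={code: None})
            if ref_mm3 == 0:
                log.warning("region %d absent in reference of %s; entry missing", code, tgt_id)
                continue
            auto_mm3 = region_volume(fused, code, dictionary={code: None})
            per_target[code][tgt_id] = {
                "jaccard": jaccard(tgt_vol, fused, code),
                "volume_error_pct": volume_error_pct(auto_mm3, ref_mm3),
            }
            manual[code].append(ref_mm3)
            auto[code].append(auto_mm3)

    results = []
    for code in codes:
        entries = per_target[code]
        if not entries:
            continue
        js = np.array([e["jaccard"] for e in entries.values()])
        ve = np.array([e["volume_error_pct"] for e in entries.values()])
        jm = float(js.mean())
        jsd = float(js.std(ddof=1)) if js.size > 1 else 0.0
        entry = PARIETAL_REGIONS.get(code)
        results.append(
            FusionRegionResult(
                code=code,
                name=entry.name if entry else f"region{code}",
                side=entry.side if entry else ("R" if code % 2 else "L"),
                mean_manual_mm3=float(np.mean(manual[code])),
                mean_auto_mm3=float(np.mean(auto[code])),
                jaccard_mean=jm,
                jaccard_sd=jsd,
                jaccard_cv_pct=100.0 * jsd / jm if jm else math.nan,
                volume_error_mean_pct=float(ve.mean()),
                n=len(entries),
            )
        )
    return FusionReport(regions=results, per_target=per_target)
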