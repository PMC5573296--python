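"""Probabilistic and maximum-probability atlas construction.

Given co-aligned label volumes in a common space, the voxelwise probability
of a region is the fraction of subjects labelled with its code there. The
maximum-probability atlas assigns each voxel the code with the largest
probability (background where all are zero, ties to the lowest code), so a
hard parcellation that accounts for all competing structures is obtained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .morphometry import DomainError
from .regions import PARIETAL_REGIONS
from .volumetry import AlignmentError, LabelVolume, TissueMask


@dataclass
class ProbabilisticMap:
    """Per-voxel subject fraction in [0, 1] for one region code."""

    grid: np.ndarray
    region_code: int
    n_subjects: int
    affine: np.ndarray
    space: str = "common"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.affine = np.asarray(self.affine, dtype=float)

    def to_nifti(self, path: str | Path) -> Path:
        img = nib.Nifti1Image(self.grid.astype(np.float32), self.affine)
        img.header.set_data_dtype(np.float32)
        img.header["descrip"] = f"code={self.region_code};n={self.n_subjects}".encode()
        nib.save(img, str(path))
        return Path(path)

    @classmethod
    def from_nifti(cls, path: str | Path, region_code: int | None = None, n_subjects: int = 0):
        img = nib.load(str(path))
        if region_code is None or not n_subjects:
            desc = img.header["descrip"].tobytes().decode(errors="ignore")
            m = re.search(r"code=(\d+);n=(\d+)", desc)
            if m:
                region_code = region_code if region_code is not None else int(m.group(1))
                n_subjects = n_subjects or int(m.group(2))
        if region_code is None:
            raise ValueError(f"{path}: region code neither given nor recoverable from header")
        data = np.asanyarray(img.dataobj).astype(float)
        return cls(grid=data, region_code=int(region_code), n_subjects=int(n_subjects),
                   affine=np.asarray(img.affine))


def _check_aligned(volumes: Sequence[LabelVolume]) -> None:
    ref = volumes[0]
    for v in volumes[1:]:
        if v.grid.shape != ref.grid.shape or not np.allclose(v.affine, ref.affine):
            raise AlignmentError("label volumes are not co-aligned (shape/affine mismatch)")


def build_probabilistic_map(
    labels: Sequence[LabelVolume],
    code: int,
    masks: Sequence[TissueMask] | None = None,
) -> ProbabilisticMap:
    """Voxelwise fraction of subjects carrying ``code``.

    With ``masks`` given (one per subject), each subject's label raster is
    restricted to its grey-matter mask *before* averaging — per-subject
    masking then averaging, matching tissue masks applied to the individual
    delineations.
    """
    if len(labels) == 0:
        raise DomainError("need at least one label volume")
    _check_aligned(labels)
    if masks is not None:
        if len(masks) != len(labels):
            raise DomainError("need one mask per label volume")
        for v, m in zip(labels, masks):
            if v.grid.shape != m.grid.shape:
                raise AlignmentError("mask/label shape mismatch")
    count = np.zeros(labels[0].grid.shape, dtype=np.int32)
    for i, v in enumerate(labels):
        hit = v.grid == code
        if masks is not None:
            hit = hit & (masks[i].grid == 1)
        count += hit
    n = len(labels)
    return ProbabilisticMap(grid=count / n, region_code=int(code), n_subjects=n,
                            affine=labels[0].affine, space="common")


def build_probabilistic_atlas(
    labels: Sequence[LabelVolume],
    codes: Sequence[int] | None = None,
    masks: Sequence[TissueMask] | None = None,
) -> dict[int, ProbabilisticMap]:
    """Probabilistic maps for each region code (defaults to the parietal set)."""
    codes = list(codes) if codes is not None else sorted(PARIETAL_REGIONS)
    return {int(c): build_probabilistic_map(labels, c, masks=masks) for c in codes}


def apply_gm_mask_map(pmap: ProbabilisticMap, mask: TissueMask) -> ProbabilisticMap:
    """Zero a probability map outside a template-space mask (mask *after* averaging)."""
    if pmap.grid.shape != mask.grid.shape:
        raise AlignmentError(f"shape mismatch: map {pmap.grid.shape} vs mask {mask.grid.shape}")
    return ProbabilisticMap(
        grid=pmap.grid * (mask.grid == 1),
        region_code=pmap.region_code,
        n_subjects=pmap.n_subjects,
        affine=pmap.affine,
        space=pmap.space,
    )


def build_max_prob_atlas(maps: Sequence[ProbabilisticMap]) -> LabelVolume:
    """Argmax parcellation over regional probability maps.

    Voxels where every probability is zero stay background (0); ties go to
    the lowest region code (a documented convention — the construction rule
    itself only fixes the argmax).
    """
    if len(maps) == 0:
        raise DomainError("need at least one probabilistic map")
    codes = [m.region_code for m in maps]
    if len(set(codes)) != len(codes):
        raise DomainError(f"duplicate region codes: {sorted(codes)}")
    order = np.argsort(codes, kind="stable")
    maps = [maps[i] for i in order]
    ref = maps[0]
    for m in maps[1:]:
        if m.grid.shape != ref.grid.shape or not np.allclose(m.affine, ref.affine):
            raise AlignmentError("probability maps are not co-aligned")
    stack = np.stack([m.grid for m in maps])
    best = np.argmax(stack, axis=0)  # first (= lowest code) maximum wins
    out = np.asarray([m.region_code for m in maps], dtype=np.int32)[best]
    out[stack.max(axis=0) == 0] = 0
    return LabelVolume(grid=out, affine=ref.affine, space="common")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned world-coordinate box (mm); lo/hi are inclusive voxel-centre bounds."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]


def probability_extent(pmap: ProbabilisticMap, threshold: float) -> BoundingBox | None:
    """World-space bounding box of voxels with probability >= threshold.

    Returns None when no voxel reaches the threshold.
    """
    if not 0 < threshold <= 1:
        raise DomainError(f"threshold must be in (0, 1], got {threshold}")
    idx = np.argwhere(pmap.grid >= threshold)
    if idx.size == 0:
        return None
    homog = np.c_[idx, np.ones(len(idx))]
    world = homog @ pmap.affine.T
    world = world[:, :3]
    return BoundingBox(lo=tuple(world.min(axis=0)), hi=tuple(world.max(axis=0)))


def save_probabilistic_atlas(maps: dict[int, ProbabilisticMap], out_dir: str | Path) -> list[Path]:
    """Write maps as ``prob_<code>_<name>.nii.gz`` files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for code in sorted(maps):
        name = PARIETAL_REGIONS[code].name if code in PARIETAL_REGIONS else f"region{code}"
        paths.append(maps[code].to_nifti(out / f"prob_{code}_{name}.nii.gz"))
    return paths


def load_probabilistic_atlas(prob_dir: str | Path) -> dict[int, ProbabilisticMap]:
    """Load every ``prob_<code>_*.nii.gz`` map from a directory."""
    maps: dict[int, ProbabilisticMap] = {}
    for p in sorted(Path(prob_dir).glob("prob_*.nii*")):
        code = int(p.name.split("_")[1])
        maps[code] = ProbabilisticMap.from_nifti(p, region_code=code)
    if not maps:
        raise FileNotFoundError(f"no prob_*.nii[.gz] maps found in {prob_dir}")
    return maps
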