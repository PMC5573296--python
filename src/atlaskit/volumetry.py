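"""Label-volume containers and region volumetry.

A :class:`LabelVolume` is a 3D integer grid of region codes (0 = background)
with a voxel-to-world affine and a space tag (``native`` or ``common``).
Volumes are obtained by voxel counting times the voxel volume; grey-matter
restricted volumes multiply the label raster with a binary tissue mask, as
done when intersecting manual delineations with a tissue classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import stats

from .morphometry import DomainError, round_half_up
from .regions import PARIETAL_REGIONS, codes_for_side

log = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class LabelVolume:
    """3D integer raster of region codes with world geometry."""

    grid: np.ndarray
    affine: np.ndarray
    space: str = "native"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"grid must be integer-typed, got {self.grid.dtype}")
        self.affine = _check_affine(self.affine)
        if self.space not in ("native", "common"):
            raise ValueError(f"space must be 'native' or 'common', got {self.space!r}")

    @property
    def voxel_dims(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine's spatial columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def codes(self) -> list[int]:
        """Distinct nonzero codes present in the raster."""
        return [int(c) for c in np.unique(self.grid) if c != 0]

    def same_grid(self, other: "LabelVolume | TissueMask") -> bool:
        return self.grid.shape == other.grid.shape and np.allclose(self.affine, other.affine)

    # -- NIfTI I/O ----------------------------------------------------------

    def to_nifti(self, path: str | Path) -> Path:
        img = nib.Nifti1Image(self.grid.astype(np.int16), self.affine)
        img.header.set_data_dtype(np.int16)
        nib.save(img, str(path))
        return Path(path)

    @classmethod
    def from_nifti(cls, path: str | Path, space: str = "native") -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        grid = np.rint(data).astype(np.int32)
        return cls(grid=grid, affine=np.asarray(img.affine), space=space)


@dataclass
class TissueMask:
    """Binary raster aligned with a label volume (1 = tissue of interest)."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.grid.shape}")
        vals = np.unique(self.grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")
        self.grid = self.grid.astype(np.uint8)
        self.affine = _check_affine(self.affine)

    def to_nifti(self, path: str | Path) -> Path:
        img = nib.Nifti1Image(self.grid.astype(np.uint8), self.affine)
        img.header.set_data_dtype(np.uint8)
        nib.save(img, str(path))
        return Path(path)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "TissueMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        return cls(grid=(np.rint(data) > 0).astype(np.uint8), affine=np.asarray(img.affine))


# -- volumetric operations --------------------------------------------------


def region_volume(vol: LabelVolume, code: int, dictionary: Mapping[int, object] | None = None) -> float:
    """Volume in mm^3 of one region: voxel count times voxel volume."""
    dictionary = dictionary if dictionary is not None else PARIETAL_REGIONS
    if code not in dictionary:
        raise DomainError(f"unknown region code {code}")
    n = int((vol.grid == code).sum())
    if n == 0:
        log.warning("region code %d has zero voxels", code)
    return n * vol.voxel_volume


def gm_masked_volume(
    vol: LabelVolume, mask: TissueMask, code: int, dictionary: Mapping[int, object] | None = None
) -> float:
    """Volume of a region restricted to the grey-matter mask; <= region_volume."""
    if vol.grid.shape != mask.grid.shape:
        raise AlignmentError(f"shape mismatch: labels {vol.grid.shape} vs mask {mask.grid.shape}")
    dictionary = dictionary if dictionary is not None else PARIETAL_REGIONS
    if code not in dictionary:
        raise DomainError(f"unknown region code {code}")
    n = int(((vol.grid == code) & (mask.grid == 1)).sum())
    return n * vol.voxel_volume


def extract_volumes(
    vol: LabelVolume, codes: Sequence[int], mask: TissueMask | None = None
) -> dict[int, float]:
    """Per-code volumes (optionally grey-matter masked) for a set of regions."""
    if mask is None:
        return {int(c): region_volume(vol, c) for c in codes}
    return {int(c): gm_masked_volume(vol, mask, c) for c in codes}


def lobe_total(region_volumes: Mapping[int, float], side: str) -> float:
    """Whole-lobe volume for one hemisphere: sum of the four ipsilateral regions."""
    codes = codes_for_side(side)
    missing = [c for c in codes if c not in region_volumes]
    if missing:
        raise DomainError(f"missing region volumes for codes {missing}")
    return float(sum(region_volumes[c] for c in codes))


def percent_of_lobe(region_mm3: float, lobe_mm3: float) -> int:
    """Region volume as an integer (half-up) percentage of the ipsilateral lobe."""
    if lobe_mm3 <= 0:
        raise DomainError(f"lobe volume must be > 0, got {lobe_mm3}")
    return int(round_half_up(100.0 * region_mm3 / lobe_mm3))


def asymmetry_pct(mean_a: float, mean_b: float) -> float:
    """How much larger mean_a is than mean_b, as a percentage to 1 decimal."""
    if mean_b <= 0:
        raise DomainError(f"reference mean must be > 0, got {mean_b}")
    return round_half_up(100.0 * (mean_a - mean_b) / mean_b, 1)


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired two-tailed t-test over subject-aligned samples."""

    t: float
    p: float
    n: int

    @property
    def significant_05(self) -> bool:
        return self.p < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p < 0.01


def paired_lr_test(left: Sequence[float], right: Sequence[float]) -> PairedTestResult:
    """Paired two-tailed Student's t-test of left vs right volumes (n-1 df).

    Degenerate zero-variance differences are reported exactly: t = 0, p = 1
    for identical vectors, t = +/-inf, p = 0 for a constant nonzero offset.
    """
    a = np.asarray(left, dtype=float)
    b = np.asarray(right, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise DomainError("need at least 2 paired observations")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTestResult(t=0.0, p=1.0, n=a.size)
        return PairedTestResult(t=float(np.sign(d.mean()) * np.inf), p=0.0, n=a.size)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p), n=a.size)
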