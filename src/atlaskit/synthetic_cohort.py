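"""Synthetic 3D label cohort and feature table with planted statistical structure.

The generator emulates the inputs the pipeline expects from a real study:

* a template "parietal lobe" modelled as an ellipsoidal cortical shell split
  into four angular sectors per hemisphere (codes from the region
  dictionary), with the right-hemisphere sectors displaced anteriorly by a
  configurable torque shift (the physiological brain torque);
* per subject, a global scale factor (an intracranial-volume proxy carrying
  a gender effect) and a smooth, invertible random deformation (Gaussian-
  smoothed displacement field), applied by pull-back so the exact forward
  and backward world-coordinate maps are known and can serve as an oracle
  registration;
* a grey-matter mask covering the outer half of the shell band;
* a per-subject feature table with the reference tables' schema, whose
  key variable pairs (gender~ICV, region volume~additional gyri, PISJ~age)
  carry planted Spearman correlations via Gaussian copulas, calibrated so
  the *observed* rank correlation matches the target despite median-split
  and discretisation attenuation.

Sectors are deliberately schematic rather than anatomically shaped: every
pipeline operator is geometry-agnostic, so statistical fidelity of the
cohort takes priority over gyral realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage, stats

from .cohort_tables import CohortTable, HemiFeatureRecord, SubjectRecord
from .morphometry import classify_sulcus_length, sulcus_extent_pct
from .volumetry import LabelVolume, TissueMask

# sector code layout: quadrants of (anterior y, superior z); +1 = right
_SECTOR_BASES = {
    (True, True): 60,   # anterior-superior: postCG
    (True, False): 84,  # anterior-inferior: SMG
    (False, True): 62,  # posterior-superior: supPL
    (False, False): 32, # posterior-inferior: AG
}

#: axis anisotropy of the outer shell (x, y, z) relative to ``shell_outer_mm``
_AXIS_RATIOS = (1.15, 1.0, 0.9)

#: mean MNI-space table volumes (mm^3) the feature table is scaled toward
_TABLE_VOLUME_TARGETS = {(84, "L"): 36194.0, (85, "R"): 33053.0,
                         (32, "L"): 20805.0, (33, "R"): 22406.0}

#: per-hemisphere rates of the binary morphology scores (L, R)
_BINARY_RATES = {"ips_continuous": (0.53, 0.23), "ips_pcg_connected": (0.87, 0.90),
                 "as_ips_connected": (0.20, 0.37)}

#: PISJ prominence class probabilities (absent, dimple, vague, prominent)
_PISJ_PROBS = np.array([0.02, 0.10, 0.23, 0.65])

_TEMPLATE_ICV_CM3 = 1466.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic cohort."""

    seed: int = 0
    n_subjects: int = 30
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 2.0
    shell_inner_mm: float = 21.0
    shell_outer_mm: float = 32.0
    deform_amplitude_mm: float = 2.0
    deform_smoothness_mm: float = 8.0
    torque_shift_mm: float = 8.0
    gender_icv_rho: float = -0.7
    volume_gyri_rho: float = 0.6
    pisj_age_rho: float = 0.5
    scale_log_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 < self.shell_inner_mm < self.shell_outer_mm:
            raise ValueError("need 0 < shell_inner_mm < shell_outer_mm")
        half_extent = min(n * self.voxel_mm for n in self.grid_shape) / 2.0
        reach = self.shell_outer_mm * max(_AXIS_RATIOS) * 1.15 + self.torque_shift_mm
        if reach > half_extent:
            raise ValueError(
                f"shell (reach ~{reach:.0f} mm) exceeds the grid half-extent {half_extent:.0f} mm"
            )
        if self.deform_amplitude_mm < 0 or self.torque_shift_mm < 0:
            raise ValueError("amplitudes must be >= 0")
        for rho in (self.gender_icv_rho, self.volume_gyri_rho, self.pisj_age_rho):
            if not -1 <= rho <= 1:
                raise ValueError(f"target rank correlations must be in [-1, 1], got {rho}")

    @property
    def affine(self) -> np.ndarray:
        """RAS affine with the world origin at the grid centre."""
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.voxel_mm
        aff[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_mm
        return aff

    @property
    def outer_semi_axes(self) -> np.ndarray:
        return self.shell_outer_mm * np.asarray(_AXIS_RATIOS)

    @property
    def inner_fraction(self) -> float:
        return self.shell_inner_mm / self.shell_outer_mm

    def sector_volume_mm3(self) -> float:
        """Analytic template volume of one sector (identical for all eight)."""
        a, b, c = self.outer_semi_axes
        q = self.inner_fraction
        return 4.0 / 3.0 * np.pi * a * b * c * (1.0 - q**3) / 8.0


# -- template geometry -------------------------------------------------------


def _template_fields(pts: np.ndarray, config: SyntheticConfig):
    """Label code and grey-matter flag of the template at (3, N) world points."""
    x, y, z = pts
    yy = np.where(x >= 0, y - config.torque_shift_mm, y)
    a, b, c = config.outer_semi_axes
    rho = np.sqrt((x / a) ** 2 + (yy / b) ** 2 + (z / c) ** 2)
    q = config.inner_fraction
    in_shell = (rho >= q) & (rho <= 1.0)
    base = np.zeros(x.shape, dtype=np.int32)
    for (ant, sup), code in _SECTOR_BASES.items():
        sel = ((yy >= 0) == ant) & ((z >= 0) == sup)
        base[sel] = code
    labels = np.where(in_shell, base + (x >= 0).astype(np.int32), 0)
    gm = in_shell & (rho >= (1.0 + q) / 2.0)
    return labels, gm.astype(np.uint8)


def template_label(pts: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    return _template_fields(pts, config)[0]


# -- copula calibration ------------------------------------------------------


def latent_rho_for_median_split(target: float) -> float:
    """Latent normal correlation yielding Spearman ``target`` against a
    median-split binary variable (closed form via the orthant probability)."""
    limit = np.sqrt(0.75)
    if abs(target) > limit:
        raise ValueError(f"|rho| <= {limit:.3f} required for a balanced binary variable")
    return float(np.sqrt(2.0) * np.sin(np.pi * target / np.sqrt(12.0)))


@lru_cache(maxsize=32)
def _calibrate_discrete(target: float, kind: str, param: float) -> float:
    """Latent correlation reproducing Spearman ``target`` against a discretised
    margin (``kind`` in {"poisson", "pisj"}), by deterministic Monte-Carlo
    bisection: discretisation averages ranks within cells and attenuates the
    observed coefficient, so the latent correlation must be inflated."""
    if target == 0.0:
        return 0.0
    rng = np.random.default_rng(123456789)
    z1 = rng.standard_normal(100_000)
    eps = rng.standard_normal(100_000)

    def quantile(u: np.ndarray) -> np.ndarray:
        if kind == "poisson":
            return stats.poisson.ppf(u, param)
        cum = np.cumsum(_PISJ_PROBS)
        return np.searchsorted(cum, u, side="left").clip(0, 3)

    def observed(rho_lat: float) -> float:
        z2 = rho_lat * z1 + np.sqrt(1 - rho_lat**2) * eps
        return stats.spearmanr(z1, quantile(stats.norm.cdf(z2))).statistic

    sign = np.sign(target)
    lo, hi = 0.0, 0.9999
    if observed(sign * hi) * sign < abs(target):
        raise ValueError(f"target rank correlation {target} infeasible for {kind} margin")
    for _ in range(30):
        mid = (lo + hi) / 2.0
        if observed(sign * mid) * sign < abs(target):
            lo = mid
        else:
            hi = mid
    return float(sign * (lo + hi) / 2.0)


def _normal_scores(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blom-type normal scores of the ranks (random tie-break for stability)."""
    order = np.argsort(x + 1e-9 * rng.standard_normal(x.shape), kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(x) + 1)
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


# -- truth bookkeeping -------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort (the oracle the tests check against)."""

    config: SyntheticConfig
    subject_ids: list[str]
    gender: np.ndarray
    scale: np.ndarray
    icv_cm3: np.ndarray
    brain_cm3: np.ndarray
    age: np.ndarray
    field_seeds: np.ndarray
    analytic_volumes_mm3: dict[int, np.ndarray]
    voxel_counts: dict[str, dict[int, int]] = field(default_factory=dict)
    fields: dict[str, np.ndarray] = field(default_factory=dict)  # subject -> (3, nx, ny, nz)

    def _index(self, subject_id: str) -> int:
        return self.subject_ids.index(subject_id)

    def _interp_field(self, subject_id: str, pts: np.ndarray) -> np.ndarray:
        """Displacement (3, N) at world points, trilinear, edge-extended."""
        u = self.fields.get(subject_id)
        if u is None:
            raise KeyError(f"no deformation field stored for {subject_id}; rasterize first")
        inv = np.linalg.inv(self.config.affine)
        vox = inv[:3, :3] @ pts + inv[:3, 3:4]
        return np.stack(
            [ndimage.map_coordinates(u[k], vox, order=1, mode="nearest") for k in range(3)]
        )

    def subject_to_template(self, subject_id: str, pts: np.ndarray) -> np.ndarray:
        """Backward map b(x) = x/s - u(x): subject world -> template world."""
        s = self.scale[self._index(subject_id)]
        return pts / s - self._interp_field(subject_id, pts)

    def template_to_subject(self, subject_id: str, pts: np.ndarray, n_iter: int = 10) -> np.ndarray:
        """Inverse of the backward map by fixed-point iteration x = s(t + u(x))."""
        s = self.scale[self._index(subject_id)]
        x = pts * s
        for _ in range(n_iter):
            x = s * (pts + self._interp_field(subject_id, x))
        return x

    # -- persistence --------------------------------------------------------

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "subject_ids": self.subject_ids,
            "gender": self.gender.tolist(),
            "scale": self.scale.tolist(),
            "icv_cm3": self.icv_cm3.tolist(),
            "brain_cm3": self.brain_cm3.tolist(),
            "age": self.age.tolist(),
            "field_seeds": self.field_seeds.tolist(),
            "analytic_volumes_mm3": {str(c): v.tolist() for c, v in self.analytic_volumes_mm3.items()},
            "voxel_counts": {sid: {str(c): n for c, n in d.items()} for sid, d in self.voxel_counts.items()},
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=1))
        if self.fields:
            fdir = out / "fields"
            fdir.mkdir(exist_ok=True)
            for sid, u in self.fields.items():
                img = nib.Nifti1Image(np.moveaxis(u, 0, -1).astype(np.float32), self.config.affine)
                nib.save(img, str(fdir / f"{sid}_deformation.nii.gz"))
        return out / "truth.json"

    @classmethod
    def load(cls, in_dir: str | Path) -> "SyntheticTruth":
        root = Path(in_dir)
        payload = json.loads((root / "truth.json").read_text())
        cfg_kw = dict(payload["config"])
        cfg_kw["grid_shape"] = tuple(cfg_kw["grid_shape"])
        truth = cls(
            config=SyntheticConfig(**cfg_kw),
            subject_ids=payload["subject_ids"],
            gender=np.array(payload["gender"], dtype=int),
            scale=np.array(payload["scale"]),
            icv_cm3=np.array(payload["icv_cm3"]),
            brain_cm3=np.array(payload["brain_cm3"]),
            age=np.array(payload["age"], dtype=int),
            field_seeds=np.array(payload["field_seeds"], dtype=np.int64),
            analytic_volumes_mm3={int(c): np.array(v) for c, v in payload["analytic_volumes_mm3"].items()},
            voxel_counts={sid: {int(c): n for c, n in d.items()} for sid, d in payload["voxel_counts"].items()},
        )
        fdir = root / "fields"
        if fdir.is_dir():
            for sid in truth.subject_ids:
                p = fdir / f"{sid}_deformation.nii.gz"
                if p.exists():
                    arr = np.asanyarray(nib.load(str(p)).dataobj).astype(np.float32)
                    truth.fields[sid] = np.moveaxis(arr, -1, 0)
        return truth


# -- sampling ----------------------------------------------------------------


def sample_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Sample the scalar ground truth (no rasterisation): scales, demographics,
    analytic region volumes, per-subject deformation seeds."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2025]))
    n = config.n_subjects

    z_icv = rng.standard_normal(n)
    rho_lat = latent_rho_for_median_split(config.gender_icv_rho)
    g_lat = rho_lat * z_icv + np.sqrt(1 - rho_lat**2) * rng.standard_normal(n)
    gender = np.zeros(n, dtype=int)
    gender[np.argsort(-g_lat, kind="stable")[: n // 2]] = 1  # top half female: balanced

    scale = np.exp(config.scale_log_sd * z_icv)
    icv = np.round(_TEMPLATE_ICV_CM3 * scale**3).astype(int)
    brain = np.round(icv * rng.uniform(0.82, 0.88, size=n)).astype(int)
    age = rng.integers(20, 55, size=n)

    sector = config.sector_volume_mm3()
    analytic = {code: sector * scale**3 for code in (32, 33, 60, 61, 62, 63, 84, 85)}

    field_seeds = rng.integers(0, 2**31 - 1, size=n)
    ids = [f"s{i + 1:03d}" for i in range(n)]
    return SyntheticTruth(
        config=config, subject_ids=ids, gender=gender, scale=scale,
        icv_cm3=icv.astype(float), brain_cm3=brain.astype(float), age=age,
        field_seeds=field_seeds, analytic_volumes_mm3=analytic,
    )


def _deformation_field(config: SyntheticConfig, seed: int) -> np.ndarray:
    """Smooth random displacement field (3, nx, ny, nz) with RMS magnitude
    equal to ``deform_amplitude_mm``."""
    shape = config.grid_shape
    if config.deform_amplitude_mm == 0:
        return np.zeros((3, *shape), dtype=np.float32)
    rng = np.random.default_rng(seed)
    sigma_vox = config.deform_smoothness_mm / config.voxel_mm
    u = rng.standard_normal((3, *shape))
    for k in range(3):
        u[k] = ndimage.gaussian_filter(u[k], sigma=sigma_vox, mode="reflect")
    rms = np.sqrt((u**2).sum(axis=0).mean())
    u *= config.deform_amplitude_mm / rms
    return u.astype(np.float32)


def generate_label_cohort(
    config: SyntheticConfig, truth: SyntheticTruth | None = None
) -> tuple[list[LabelVolume], list[TissueMask], SyntheticTruth]:
    """Rasterise the cohort's label volumes and grey-matter masks.

    Each subject's raster samples the analytic template through the
    subject's backward map b(x) = x/s - u(x); the exact maps are retained in
    the returned truth for oracle registration and invertibility checks.
    """
    truth = truth if truth is not None else sample_truth(config)
    affine = config.affine
    idx = np.indices(config.grid_shape).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]

    labels: list[LabelVolume] = []
    masks: list[TissueMask] = []
    for i, sid in enumerate(truth.subject_ids):
        u = _deformation_field(config, int(truth.field_seeds[i]))
        truth.fields[sid] = u
        t = world / truth.scale[i] - u.reshape(3, -1)
        lab, gm = _template_fields(t, config)
        grid = lab.reshape(config.grid_shape)
        labels.append(LabelVolume(grid=grid, affine=affine.copy(), space="common"))
        masks.append(TissueMask(grid=gm.reshape(config.grid_shape), affine=affine.copy()))
        codes, counts = np.unique(grid[grid > 0], return_counts=True)
        truth.voxel_counts[sid] = {int(c): int(n) for c, n in zip(codes, counts)}
    return labels, masks, truth


# -- feature table -----------------------------------------------------------


def _planted_counts(
    volumes: np.ndarray, rho: float, rng: np.random.Generator, lam: float = 3.0
) -> np.ndarray:
    """Gyri totals rank-linked to region volumes through a Gaussian copula."""
    z_v = _normal_scores(volumes, rng)
    rho_lat = _calibrate_discrete(float(rho), "poisson", lam)
    z = rho_lat * z_v + np.sqrt(1 - rho_lat**2) * rng.standard_normal(len(volumes))
    return stats.poisson.ppf(stats.norm.cdf(z), lam).astype(int)


def _planted_pisj(age: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    z_a = _normal_scores(age.astype(float), rng)
    rho_lat = _calibrate_discrete(float(rho), "pisj", 0.0)
    z = rho_lat * z_a + np.sqrt(1 - rho_lat**2) * rng.standard_normal(len(age))
    cum = np.cumsum(_PISJ_PROBS)
    return np.searchsorted(cum, stats.norm.cdf(z), side="left").clip(0, 3)


def _landmarks(n: int, rng: np.random.Generator):
    sup = np.round(rng.normal(44, 5, n)).astype(int).clip(25, 60)
    height = np.round(rng.normal(38, 5, n)).astype(int).clip(15, 60)
    inf = sup + height
    pct_raw = rng.normal(65, 18, n).clip(0, 100)
    top = np.round(inf - pct_raw / 100.0 * height).astype(int).clip(sup, inf)
    return sup, inf, top


def generate_feature_table(config: SyntheticConfig, truth: SyntheticTruth) -> CohortTable:
    """Feature table with the reference schema and planted correlations.

    SMG/AG table volumes are the truth's analytic volumes scaled to the
    MNI-space magnitudes of the study tables (which also plants the leftward
    SMG asymmetry) with independent lognormal observation noise; gyri totals
    and PISJ prominence are copula-linked to region volume and age.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7100]))
    n = config.n_subjects
    sector = config.sector_volume_mm3()

    subjects = [
        SubjectRecord(sid, float(truth.icv_cm3[i]), float(truth.brain_cm3[i]),
                      int(truth.age[i]), int(truth.gender[i]))
        for i, sid in enumerate(truth.subject_ids)
    ]

    table_vol: dict[tuple[int, str], np.ndarray] = {}
    for (code, side), target in _TABLE_VOLUME_TARGETS.items():
        noise = np.exp(rng.normal(0.0, 0.10, n))
        table_vol[(code, side)] = truth.analytic_volumes_mm3[code] / sector * target * noise

    gm_ratio = {"smg": 0.50, "ag": 0.61}
    smg_codes = {"L": 84, "R": 85}
    ag_codes = {"L": 32, "R": 33}

    pisj = {"L": _planted_pisj(truth.age, config.pisj_age_rho, rng),
            "R": _planted_pisj(truth.age, config.pisj_age_rho / 2.0, rng)}

    records: list[HemiFeatureRecord] = []
    for side_i, side in enumerate(("L", "R")):
        fields: dict[str, np.ndarray] = {}
        for name, rates in _BINARY_RATES.items():
            fields[name] = (rng.random(n) < rates[side_i]).astype(int)
        for reg, codemap in (("smg", smg_codes), ("ag", ag_codes)):
            code = codemap[side]
            gmwm = np.round(table_vol[(code, side)]).astype(int)
            gm = np.round(gmwm * np.clip(gm_ratio[reg] * np.exp(rng.normal(0, 0.04, n)), 0.2, 0.95)).astype(int)
            sup, inf, top = _landmarks(n, rng)
            pct = np.array([sulcus_extent_pct(s, i_, t) for s, i_, t in zip(sup, inf, top)])
            total = _planted_counts(table_vol[(code, side)], config.volume_gyri_rho, rng)
            split = np.stack([rng.multinomial(t, [1 / 3] * 3) for t in total])
            fields.update({
                f"{reg}_gmwm": gmwm, f"{reg}_gm": gm,
                f"{reg}_sup": sup, f"{reg}_inf": inf, f"{reg}_top": top, f"{reg}_pct": pct,
                f"{reg}_g_ant": split[:, 0], f"{reg}_g_sup": split[:, 1],
                f"{reg}_g_post": split[:, 2], f"{reg}_g_total": total,
            })
        fields["sf_long"] = np.array([classify_sulcus_length(p) for p in fields["smg_pct"]])
        fields["as_long"] = np.array([classify_sulcus_length(p) for p in fields["ag_pct"]])
        fields["pisj"] = pisj[side]
        for i, sid in enumerate(truth.subject_ids):
            records.append(HemiFeatureRecord(
                subject_id=sid, hemisphere=side,
                **{k: (float(v[i]) if k.endswith(("gmwm", "gm")) else int(v[i]))
                   for k, v in fields.items()},
            ))

    order = {sid: i for i, sid in enumerate(truth.subject_ids)}
    records.sort(key=lambda r: (order[r.subject_id], r.hemisphere))
    table = CohortTable(subjects=subjects, hemifeatures=records)
    table.validate()
    return table


def generate_null_table(seed: int, n_rows: int = 500, n_cols: int = 100):
    """Matrix of mutually independent Gaussian columns (screen null calibration)."""
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([seed, 9000]))
    data = rng.standard_normal((n_rows, n_cols))
    return pd.DataFrame(data, columns=[f"v{i:03d}" for i in range(n_cols)])
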