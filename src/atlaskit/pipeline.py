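"""End-to-end pipeline over a synthetic cohort, with a checksummed manifest.

Stages: simulate -> features -> volumes -> screen -> atlas -> fuse. Each
stage writes its artifacts under the output directory; the manifest lists
every artifact with a SHA-256 checksum so reruns with one seed can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from . import atlas_builder, label_fusion, stats_screen, volumetry
from .cohort_tables import write_cohort
from .morphometry import summarize_columns
from .regions import PARIETAL_REGIONS
from .synthetic_cohort import SyntheticConfig, SyntheticTruth, generate_feature_table, generate_label_cohort

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "features", "volumes", "screen", "atlas", "fuse")


class PipelineConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    out_dir: Path
    seed: int = 0
    n_subjects: int = 10
    alpha: float = 0.005
    provider: str = "oracle"  # oracle | identity
    stages: tuple[str, ...] = ALL_STAGES
    regions: tuple[int, ...] = tuple(sorted(PARIETAL_REGIONS))
    synthetic: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise PipelineConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise PipelineConfigError(f"unknown stage name(s): {unknown}")
        if self.provider not in ("oracle", "identity"):
            raise PipelineConfigError(f"unknown provider {self.provider!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "out_dir" not in raw:
            raise PipelineConfigError(f"{path}: 'out_dir' is required")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; return the artifact manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    syn = SyntheticConfig(seed=config.seed, n_subjects=config.n_subjects, **config.synthetic)

    labels = masks = truth = table = None
    t0 = time.monotonic()
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t_stage = time.monotonic()
        if stage == "simulate":
            labels, masks, truth = generate_label_cohort(syn)
            sim = out / "simulate"
            sim.mkdir(exist_ok=True)
            for sid, vol, msk in zip(truth.subject_ids, labels, masks):
                artifacts.append(vol.to_nifti(sim / f"{sid}_labels.nii.gz"))
                artifacts.append(msk.to_nifti(sim / f"{sid}_gm_mask.nii.gz"))
            artifacts.append(truth.save(sim))
            table = generate_feature_table(syn, truth)
            artifacts.extend(write_cohort(table, sim))
        elif stage == "features":
            table = _require(table, stage, "simulate")
            summ = summarize_columns(table.hemifeature_frame().drop(columns=["subject_id", "hemisphere"]))
            p = out / "feature_summary.csv"
            summ.to_csv(p, index_label="variable")
            artifacts.append(p)
        elif stage == "volumes":
            labels = _require(labels, stage, "simulate")
            rows = []
            for sid, vol, msk in zip(truth.subject_ids, labels, masks):
                gmwm = volumetry.extract_volumes(vol, config.regions)
                gm = volumetry.extract_volumes(vol, config.regions, mask=msk)
                for code in config.regions:
                    rows.append({"subject_id": sid, "code": code,
                                 "gmwm_mm3": gmwm[code], "gm_mm3": gm[code]})
            import pandas as pd

            p = out / "region_volumes.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            artifacts.append(p)
        elif stage == "screen":
            table = _require(table, stage, "simulate")
            hits = stats_screen.all_pairs_screen(table, alpha=config.alpha)
            p = out / "screen.csv"
            stats_screen.screen_to_frame(hits).to_csv(p, index=False)
            artifacts.append(p)
        elif stage == "atlas":
            labels = _require(labels, stage, "simulate")
            maps = atlas_builder.build_probabilistic_atlas(labels, config.regions)
            adir = out / "atlas"
            artifacts.extend(atlas_builder.save_probabilistic_atlas(maps, adir))
            maxprob = atlas_builder.build_max_prob_atlas(list(maps.values()))
            artifacts.append(maxprob.to_nifti(adir / "maxprob.nii.gz"))
        elif stage == "fuse":
            labels = _require(labels, stage, "simulate")
            grid = label_fusion.TargetGrid.of(labels[0])
            if config.provider == "oracle":
                provider = label_fusion.OracleProvider(truth, grid)
            else:
                provider = label_fusion.IdentityProvider(grid)
            report = label_fusion.leave_one_out(
                list(zip(truth.subject_ids, labels)), provider, config.regions
            )
            p = out / "fusion_report.csv"
            report.to_frame().to_csv(p, index=False)
            artifacts.append(p)
        log.info("stage %-8s done in %.1fs", stage, time.monotonic() - t_stage)

    log.info("pipeline done in %.1fs", time.monotonic() - t0)
    manifest = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "stages": list(config.stages),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _require(obj, stage: str, needed: str):
    if obj is None:
        raise PipelineConfigError(f"stage {stage!r} requires stage {needed!r} to run first")
    return obj
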