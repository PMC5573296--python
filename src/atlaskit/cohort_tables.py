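"""Per-subject cohort tables: typed records, validation, CSV I/O.

The packaged reference cohort transcribes the study's per-subject tables:
demographics (intracranial volume, brain volume, age, gender) for 30
subjects, and per-hemisphere parietal morphology (sulcal scores, slice
landmarks, additional-gyri counts, PISJ prominence) together with
supramarginal- and angular-gyrus volumes in MNI space — one left and one
right record per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd


class CohortFormatError(ValueError):
    """A cohort file does not match the expected schema."""


class CohortValidationError(ValueError):
    """A record violates a domain invariant."""

    def __init__(self, subject_id: str, field: str, message: str):
        self.subject_id = subject_id
        self.field = field
        super().__init__(f"subject {subject_id!r}, field {field!r}: {message}")


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and global brain measures for one subject.

    Volumes are in cm^3; ``gender`` is 1 for female, 0 for male.
    """

    subject_id: str
    icv: float
    brain: float
    age: int
    gender: int

    def validate(self) -> None:
        sid = self.subject_id
        if not (self.icv > self.brain > 0):
            raise CohortValidationError(sid, "icv", f"requires icv > brain > 0, got icv={self.icv}, brain={self.brain}")
        if self.age <= 0:
            raise CohortValidationError(sid, "age", f"must be positive, got {self.age}")
        if self.gender not in (0, 1):
            raise CohortValidationError(sid, "gender", f"must be 0 or 1, got {self.gender}")


@dataclass(frozen=True)
class HemiFeatureRecord:
    """Morphology scores and SMG/AG volumes for one hemisphere of one subject.

    Landmarks (``*_sup``, ``*_inf``, ``*_top``) are axial slice indices; the
    superior limit has the *smaller* index. ``*_pct`` is the sulcus vertical
    extent as an integer percentage, ``pisj`` the 0-3 prominence score of the
    primary intermediate sulcus of Jensen, and volumes are mm^3 in MNI space.
    """

    subject_id: str
    hemisphere: str
    ips_continuous: int
    ips_pcg_connected: int
    smg_gmwm: float
    smg_gm: float
    sf_long: int
    smg_sup: int
    smg_inf: int
    smg_top: int
    smg_pct: int
    smg_g_ant: int
    smg_g_sup: int
    smg_g_post: int
    smg_g_total: int
    pisj: int
    ag_gmwm: float
    ag_gm: float
    as_long: int
    ag_sup: int
    ag_inf: int
    ag_top: int
    ag_pct: int
    ag_g_ant: int
    ag_g_sup: int
    ag_g_post: int
    ag_g_total: int
    as_ips_connected: int

    _BINARY = ("ips_continuous", "ips_pcg_connected", "sf_long", "as_long", "as_ips_connected")

    def validate(self) -> None:
        sid = self.subject_id
        if self.hemisphere not in ("L", "R"):
            raise CohortValidationError(sid, "hemisphere", f"must be 'L' or 'R', got {self.hemisphere!r}")
        for name in self._BINARY:
            v = getattr(self, name)
            if v not in (0, 1):
                raise CohortValidationError(sid, name, f"must be 0 or 1, got {v}")
        if self.pisj not in (0, 1, 2, 3):
            raise CohortValidationError(sid, "pisj", f"must be in 0..3, got {self.pisj}")
        for reg in ("smg", "ag"):
            sup = getattr(self, f"{reg}_sup")
            inf = getattr(self, f"{reg}_inf")
            top = getattr(self, f"{reg}_top")
            if not (sup <= top <= inf):
                raise CohortValidationError(
                    sid, f"{reg}_top", f"landmark order violated: sup={sup}, top={top}, inf={inf}"
                )
            if not 0 <= getattr(self, f"{reg}_pct") <= 100:
                raise CohortValidationError(sid, f"{reg}_pct", "must be in 0..100")
            parts = [getattr(self, f"{reg}_g_{d}") for d in ("ant", "sup", "post")]
            if any(p < 0 for p in parts):
                raise CohortValidationError(sid, f"{reg}_g_ant", "gyri counts must be >= 0")
            total = getattr(self, f"{reg}_g_total")
            if total != sum(parts):
                raise CohortValidationError(
                    sid, f"{reg}_g_total", f"must equal ant+sup+post = {sum(parts)}, got {total}"
                )
            if not getattr(self, f"{reg}_gmwm") >= getattr(self, f"{reg}_gm") > 0:
                raise CohortValidationError(sid, f"{reg}_gm", "requires gmwm >= gm > 0")


SUBJECT_COLUMNS = [f.name for f in dc_fields(SubjectRecord)]
HEMI_COLUMNS = [f.name for f in dc_fields(HemiFeatureRecord)]

SUBJECTS_FILENAME = "table1_subjects.csv"
HEMIFEATURES_FILENAME = "tables23_hemifeatures.csv"


@dataclass
class CohortTable:
    """A validated cohort: subject records plus one L and one R feature record each."""

    subjects: list[SubjectRecord]
    hemifeatures: list[HemiFeatureRecord]

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(dup[0], "subject_id", "duplicate subject id")
        for s in self.subjects:
            s.validate()
        for h in self.hemifeatures:
            h.validate()
        seen: dict[tuple[str, str], bool] = {}
        for h in self.hemifeatures:
            key = (h.subject_id, h.hemisphere)
            if key in seen:
                raise CohortValidationError(h.subject_id, "hemisphere", f"duplicate {h.hemisphere} record")
            seen[key] = True
        for sid in ids:
            for side in ("L", "R"):
                if (sid, side) not in seen:
                    raise CohortValidationError(sid, "hemisphere", f"missing {side} record")
        for h in self.hemifeatures:
            if h.subject_id not in ids:
                raise CohortValidationError(h.subject_id, "subject_id", "hemisphere record without subject")

    # -- convenience frames -------------------------------------------------

    def subject_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.subjects], columns=SUBJECT_COLUMNS)

    def hemifeature_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(h) for h in self.hemifeatures], columns=HEMI_COLUMNS)

    def hemi_frame(self, side: str) -> pd.DataFrame:
        """Feature rows of one hemisphere, indexed by subject in cohort order."""
        df = self.hemifeature_frame()
        df = df[df.hemisphere == side].set_index("subject_id")
        return df.loc[[s.subject_id for s in self.subjects]]

    def wide_frame(self) -> pd.DataFrame:
        """One row per subject: demographics plus L_/R_-prefixed hemisphere features.

        This is the variable-by-subject matrix the correlation screen consumes.
        """
        subj = self.subject_frame().set_index("subject_id")
        out = [subj]
        for side in ("L", "R"):
            h = self.hemi_frame(side).drop(columns=["hemisphere"])
            out.append(h.add_prefix(f"{side}_"))
        return pd.concat(out, axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.subjects == other.subjects and self.hemifeatures == other.hemifeatures


def _check_header(df: pd.DataFrame, expected: list[str], path: Path) -> None:
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        offending = (missing + extra or ["<column order>"])[0]
        raise CohortFormatError(
            f"{path}: header does not match schema (offending column: {offending!r}; "
            f"missing={missing}, unexpected={extra})"
        )


def _read_csv(path: Path, expected: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: empty file") from exc
    _check_header(df, expected, path)
    return df


def _resolve(path: str | Path, default_name: str) -> Path:
    p = Path(path)
    return p / default_name if p.is_dir() else p


def read_cohort(
    subjects_path: str | Path,
    hemifeatures_path: str | Path | None = None,
) -> CohortTable:
    """Read and fully validate a cohort from CSV.

    ``subjects_path`` may be a directory containing the two canonically named
    files (``table1_subjects.csv``, ``tables23_hemifeatures.csv``), or the
    subjects CSV with ``hemifeatures_path`` given explicitly.
    """
    p = Path(subjects_path)
    if p.is_dir():
        subj_p = p / SUBJECTS_FILENAME
        hemi_p = p / HEMIFEATURES_FILENAME
    else:
        if hemifeatures_path is None:
            raise ValueError("hemifeatures_path required when subjects_path is a file")
        subj_p, hemi_p = p, Path(hemifeatures_path)

    sdf = _read_csv(subj_p, SUBJECT_COLUMNS)
    hdf = _read_csv(hemi_p, HEMI_COLUMNS)
    subjects = [
        SubjectRecord(str(r.subject_id), float(r.icv), float(r.brain), int(r.age), int(r.gender))
        for r in sdf.itertuples(index=False)
    ]
    hemifeatures = []
    for r in hdf.itertuples(index=False):
        kw = r._asdict()
        kw["subject_id"] = str(kw["subject_id"])
        kw["hemisphere"] = str(kw["hemisphere"])
        for f in dc_fields(HemiFeatureRecord):
            if f.type in ("int",):
                kw[f.name] = int(kw[f.name]) if f.name not in ("subject_id", "hemisphere") else kw[f.name]
            elif f.type in ("float",):
                kw[f.name] = float(kw[f.name])
        hemifeatures.append(HemiFeatureRecord(**kw))
    table = CohortTable(subjects, hemifeatures)
    table.validate()
    return table


def write_cohort(table: CohortTable, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a cohort to ``out_dir`` as the two canonical CSV files.

    Round-trips with :func:`read_cohort`: ``read_cohort(write_cohort(t)) == t``.
    """
    table.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj_p = out / SUBJECTS_FILENAME
    hemi_p = out / HEMIFEATURES_FILENAME
    table.subject_frame().to_csv(subj_p, index=False)
    table.hemifeature_frame().to_csv(hemi_p, index=False)
    return subj_p, hemi_p


def load_reference_cohort() -> CohortTable:
    """Load the packaged 30-subject reference cohort."""
    data = resources.files("atlaskit") / "data"
    with resources.as_file(data) as d:
        return read_cohort(d)


def load_reference_volume_stats() -> pd.DataFrame:
    """Cohort-level region volume statistics (mean/SD/CV%/percent-of-lobe)
    per space (native/MNI), tissue class and hemisphere."""
    with resources.as_file(resources.files("atlaskit") / "data" / "table4_volume_stats.csv") as p:
        return pd.read_csv(p)


def load_reference_fusion_results() -> pd.DataFrame:
    """Published leave-one-out label-fusion metrics (region means only;
    per-subject values were never released)."""
    with resources.as_file(resources.files("atlaskit") / "data" / "table11_fusion_results.csv") as p:
        return pd.read_csv(p)


def iter_sulcus_rows(table: CohortTable) -> Iterable[tuple[str, str, str, int, int, int, int, int]]:
    """Yield (subject, hemisphere, region, sup, inf, top, printed_pct, printed_flag)
    for every sulcus of every hemisphere record (SMG's Sylvian fissure and AG's
    angular sulcus)."""
    for h in table.hemifeatures:
        for reg, flag in (("smg", h.sf_long), ("ag", h.as_long)):
            yield (
                h.subject_id,
                h.hemisphere,
                reg,
                getattr(h, f"{reg}_sup"),
                getattr(h, f"{reg}_inf"),
                getattr(h, f"{reg}_top"),
                getattr(h, f"{reg}_pct"),
                flag,
            )
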