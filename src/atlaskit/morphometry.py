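"""Morphological scoring of parietal sulci and cohort summary statistics.

The vertical extent of the Sylvian fissure (within SMG) or the angular
sulcus (within AG) is scored from three axial slice landmarks: the region's
superior limit ``sup``, its inferior limit ``inf`` (slice indices increase
inferiorly), and the superior end ``top`` of the sulcus. The extent is the
sulcus height as a percentage of the region height,

    pct = 100 * (inf - top) / (inf - sup),

rounded half-up to an integer; a sulcus is classified *long* when it spans
at least half the region height (pct >= 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class DomainError(ValueError):
    """An operation was called outside its domain."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from the floor (0.5 -> 1), unlike banker's rounding."""
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def sulcus_extent_pct(sup: int, inf: int, top: int) -> int:
    """Sulcus vertical extent as integer percent of the region height.

    ``sup < inf`` (slices count downward) and ``sup <= top <= inf`` required.
    """
    if sup >= inf:
        raise DomainError(f"requires sup < inf, got sup={sup}, inf={inf}")
    if not sup <= top <= inf:
        raise DomainError(f"top={top} outside [sup={sup}, inf={inf}]")
    return int(round_half_up(100.0 * (inf - top) / (inf - sup)))


def classify_sulcus_length(pct: int) -> int:
    """1 (long) iff the sulcus spans at least half the region height.

    The boundary value pct = 50 is classified long; the protocol wording
    ("<50%" = short) leaves the exact boundary open and this convention is
    documented.
    """
    if not 0 <= pct <= 100:
        raise DomainError(f"pct must be in 0..100, got {pct}")
    return int(pct >= 50)


def total_additional_gyri(ant: int, sup: int, post: int) -> int:
    """Total count of gyri additional to the classical horseshoe shape."""
    if min(ant, sup, post) < 0:
        raise DomainError(f"counts must be >= 0, got ({ant}, {sup}, {post})")
    return ant + sup + post


@dataclass(frozen=True)
class CohortSummary:
    """Footer-row statistics for one cohort variable.

    ``cv_pct`` is the coefficient of variation 100*sd/mean (None when the
    mean is zero); ``sum_pct`` is the integer percentage of subjects scoring
    1 and is populated for binary variables only.
    """

    mean: float
    sd: float
    cv_pct: float | None
    median: float
    sum_pct: int | None
    n: int


def cohort_summary(values, kind: str = "continuous") -> CohortSummary:
    """Mean, sample SD (n-1 denominator), CV%, median and (binary) Sum%.

    ``kind`` is one of {"continuous", "binary", "ordinal"}; binary input must
    be 0/1-valued. The median for even n is the midpoint of the two central
    order statistics.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("empty input")
    if kind not in ("continuous", "binary", "ordinal"):
        raise DomainError(f"unknown kind {kind!r}")
    if kind == "binary" and not np.isin(x, (0.0, 1.0)).all():
        raise DomainError("binary summary requires 0/1 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size >= 2 else 0.0
    cv = None if mean == 0 else 100.0 * sd / mean
    med = float(np.median(x))
    sum_pct = int(round_half_up(100.0 * x.sum() / x.size)) if kind == "binary" else None
    return CohortSummary(mean=mean, sd=sd, cv_pct=cv, median=med, sum_pct=sum_pct, n=int(x.size))


#: Variable kinds of the hemisphere feature table, used when summarising whole tables.
HEMI_KINDS = {
    "ips_continuous": "binary",
    "ips_pcg_connected": "binary",
    "sf_long": "binary",
    "as_long": "binary",
    "as_ips_connected": "binary",
    "pisj": "ordinal",
}


def summarize_columns(df, kinds: dict[str, str] | None = None):
    """Footer table (one row per numeric column) for a feature DataFrame.

    Returns a DataFrame with columns mean/sd/cv_pct/median/sum_pct/n, mirroring
    the per-column footer rows of the source tables.
    """
    import pandas as pd

    kinds = {**HEMI_KINDS, **(kinds or {})}
    rows = {}
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            continue
        s = cohort_summary(df[col].to_numpy(), kinds.get(col, "continuous"))
        rows[col] = {
            "mean": s.mean,
            "sd": s.sd,
            "cv_pct": s.cv_pct,
            "median": s.median,
            "sum_pct": s.sum_pct,
            "n": s.n,
        }
    return pd.DataFrame(rows).T
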