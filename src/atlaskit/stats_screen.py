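"""All-pairs Spearman correlation screen over cohort variables.

Every unordered pair of numeric cohort variables (demographics plus
hemisphere features, binary and ordinal variables entering as-is with
average ranks) is rank-correlated; pairs with a two-sided p below the
screening threshold (default 0.005, uncorrected, mirroring the study's
fixed reporting cut-off) are returned sorted by p. Pairs that are coupled
by construction — a derived column against one of its own inputs, such as a
gyri total against its addends or a sulcus percentage against its own
landmarks — are flagged so downstream reporting can set them aside.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_tables import CohortTable
from .morphometry import DomainError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between two named cohort variables."""

    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    trivial: bool = False

    @property
    def missing(self) -> bool:
        return math.isnan(self.r)


def spearman(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation with ties averaged and the t-approximation p.

    The p-value follows the standard two-sided t approximation
    ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom. A constant
    input leaves the correlation undefined; it is reported as missing (NaN).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise DomainError(f"need n >= 3 pairs, got {a.size}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return CorrelationResult(var_x, var_y, float("nan"), float("nan"), int(a.size))
    r, p = stats.spearmanr(a, b)
    if math.isnan(r):
        return CorrelationResult(var_x, var_y, float("nan"), float("nan"), int(a.size))
    # exact +/-1 correlations degenerate the t statistic; p underflows to 0
    if abs(r) == 1.0:
        p = 0.0
    return CorrelationResult(var_x, var_y, float(r), float(p), int(a.size))


def _same_feature(a: str, b: str) -> tuple[str, str, str, str] | None:
    """Split 'L_smg_pct'-style names into (side, region, field) when both share
    side and region; return (side, region, field_a, field_b) or None."""
    pa, pb = a.split("_", 2), b.split("_", 2)
    if len(pa) < 3 or len(pb) < 3:
        return None
    if pa[0] != pb[0] or pa[1] != pb[1] or pa[0] not in ("L", "R"):
        return None
    return pa[0], pa[1], pa[2], pb[2]


def trivially_coupled(a: str, b: str) -> bool:
    """True for pairs coupled by arithmetic construction rather than anatomy.

    Within one hemisphere and region: the gyri total vs any of its addends,
    the sulcus extent percentage vs any of its own three landmarks, the
    length class vs the percentage it thresholds, and the nested GM+WM vs
    GM-only volumes. Across regions of one hemisphere, the two inferior
    limits (one shared lobe landmark recorded in both region blocks).
    """
    split = _same_feature(a, b)
    if split is not None:
        _, _, fa, fb = split
        pair = {fa, fb}
        if "g_total" in pair and pair & {"g_ant", "g_sup", "g_post"}:
            return True
        if "pct" in pair and pair & {"sup", "inf", "top"}:
            return True
        if pair == {"gmwm", "gm"}:
            return True
    for side in ("L", "R"):
        if {a, b} == {f"{side}_smg_inf", f"{side}_ag_inf"}:
            return True
    # sf_long/as_long carry their own un-prefixed names: handled separately
    return False


_LENGTH_FLAG_OF = {"sf_long": "smg_pct", "as_long": "ag_pct"}


def _flag_coupled(a: str, b: str) -> bool:
    for side in ("L", "R"):
        for flag, pct in _LENGTH_FLAG_OF.items():
            pair = {a, b}
            if pair == {f"{side}_{flag}", f"{side}_{pct}"}:
                return True
    return False


def all_pairs_screen(
    table: CohortTable | pd.DataFrame,
    alpha: float = 0.005,
) -> list[CorrelationResult]:
    """Screen every unordered variable pair; return those with p < alpha, by p.

    Accepts a validated :class:`CohortTable` (screened on its wide per-subject
    matrix) or any numeric DataFrame. Constant columns and pairs with fewer
    than 3 complete observations are skipped with a log entry.
    """
    if not 0 <= alpha < 1:
        raise DomainError(f"alpha must be in [0, 1), got {alpha}")
    if isinstance(table, CohortTable):
        df = table.wide_frame()
    else:
        df = table
    df = df.select_dtypes(include=[np.number])
    hits: list[CorrelationResult] = []
    for ca, cb in itertools.combinations(df.columns, 2):
        sub = df[[ca, cb]].dropna()
        if len(sub) < 3:
            log.info("pair (%s, %s) skipped: fewer than 3 complete pairs", ca, cb)
            continue
        res = spearman(sub[ca], sub[cb], ca, cb)
        if res.missing:
            log.info("pair (%s, %s) skipped: constant column", ca, cb)
            continue
        if res.p < alpha:
            triv = trivially_coupled(ca, cb) or _flag_coupled(ca, cb)
            hits.append(
                CorrelationResult(res.var_x, res.var_y, res.r, res.p, res.n, trivial=triv)
            )
    hits.sort(key=lambda h: (h.p, h.var_x, h.var_y))
    return hits


def screen_to_frame(results: list[CorrelationResult], n_pairs_tested: int | None = None) -> pd.DataFrame:
    """Tabulate screen hits; the Bonferroni column is informational only."""
    df = pd.DataFrame(
        [
            {"var_x": r.var_x, "var_y": r.var_y, "r": r.r, "p": r.p, "n": r.n, "trivial": r.trivial}
            for r in results
        ],
        columns=["var_x", "var_y", "r", "p", "n", "trivial"],
    )
    if n_pairs_tested:
        df["p_bonferroni"] = (df["p"] * n_pairs_tested).clip(upper=1.0)
    return df
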