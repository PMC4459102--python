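"""Collagen isotope QC and niche-overlap analysis.

Collagen preservation is screened by the atomic C/N ratio
(pctC/12.011)/(pctN/14.007): values within 2.9-3.6 (inclusive)
indicate reliable d13C/d15N measurements.  Group niches in the
(d13C, d15N) plane are compared as convex hulls; the overlap score is
area(intersection)/area(union), and query specimens can be classified
inside/outside each group's hull — making the visual "falls inside the
cluster" argument a computable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

_C_MASS, _N_MASS = 12.011, 14.007


@dataclass
class QCParams:
    cn_min: float = 2.9
    cn_max: float = 3.6

    def __post_init__(self) -> None:
        if not self.cn_min < self.cn_max:
            raise ValueError("cn_min < cn_max required")


def cn_atomic(df: pd.DataFrame) -> pd.Series:
    """Atomic C/N ratio from weight percent columns (never user-supplied)."""
    return (df["pctC"] / _C_MASS) / (df["pctN"] / _N_MASS)


def qc_filter(records: pd.DataFrame, params: QCParams | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (retained, rejected-with-reason).

    Retained iff cn_min <= C/N_atomic <= cn_max (bounds inclusive);
    records missing pctC/pctN are flagged unassessable and rejected.
    """
    params = params or QCParams()
    df = records.copy()
    assessable = df["pctC"].notna() & df["pctN"].notna() & (df["pctN"] > 0)
    df["cn_atomic"] = np.where(assessable, cn_atomic(df), np.nan)
    ok = assessable & df["cn_atomic"].between(params.cn_min, params.cn_max)
    rejected = df[~ok].copy()
    rejected["reason"] = np.where(
        ~assessable[~ok], "unassessable",
        np.where(rejected["cn_atomic"] < params.cn_min, "cn_below_range",
                 "cn_above_range"),
    )
    return df[ok].copy(), rejected


def group_summary(records: pd.DataFrame,
                  by: tuple[str, ...] = ("taxon", "period")) -> pd.DataFrame:
    """Per-group mean/sd/n of d13C and d15N; sd is NaN below n=2."""
    if records.empty:
        raise ValueError("no records to summarize")
    g = records.groupby(list(by))
    out = g.agg(
        n=("d13C", "size"),
        mean_d13C=("d13C", "mean"), sd_d13C=("d13C", "std"),
        mean_d15N=("d15N", "mean"), sd_d15N=("d15N", "std"),
    ).reset_index()
    return out


def _hull(points: np.ndarray):
    """Convex hull as a shapely geometry; degenerate inputs flagged.

    Returns (geometry, degenerate_flag).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("hull construction needs >= 3 points per group")
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts)
        return Polygon(pts[hull.vertices]), False
    except QhullError:
        # collinear: fall back to the covering segment
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        return LineString([pts[order[0]], pts[order[-1]]]), True


@dataclass
class OverlapResult:
    score: float
    degenerate: bool
    inside_a: dict[str, bool]
    inside_b: dict[str, bool]


def overlap_score(group_a: np.ndarray, group_b: np.ndarray,
                  queries: dict[str, tuple[float, float]] | None = None
                  ) -> OverlapResult:
    """Convex-hull overlap of two isotope clusters, in [0, 1].

    Overlap = area(intersection)/area(union); for degenerate
    (collinear) clusters the ratio falls back to intersection/union of
    segment lengths and the result is flagged.  ``queries`` are
    classified inside/outside each hull (boundary counts as inside).
    """
    ha, da = _hull(group_a)
    hb, db = _hull(group_b)
    degenerate = da or db
    inter = ha.intersection(hb)
    union = ha.union(hb)
    if degenerate:
        score = inter.length / union.length if union.length > 0 else 1.0
        if ha.geom_type == "Polygon" or hb.geom_type == "Polygon":
            # mixed polygon/segment: a segment has zero area
            score = 0.0 if inter.is_empty else score
    else:
        score = inter.area / union.area if union.area > 0 else 1.0
    inside_a, inside_b = {}, {}
    for name, (x, y) in (queries or {}).items():
        p = Point(x, y)
        inside_a[name] = bool(ha.distance(p) < 1e-12)
        inside_b[name] = bool(hb.distance(p) < 1e-12)
    return OverlapResult(float(score), degenerate, inside_a, inside_b)


def group_points(records: pd.DataFrame, taxon: str, period: str) -> np.ndarray:
    sel = records[(records["taxon"] == taxon) & (records["period"] == period)]
    return sel[["d13C", "d15N"]].to_numpy(dtype=float)
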