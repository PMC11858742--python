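"""Spatial range estimation: grid-cell occupancy, convex-hull geographic
range size on the sphere, latitudinal ranges, and subset-vs-total
overlap/added statistics.

All areas are spherical-polygon areas on the authalic Earth radius
(6371.0088 km).  Hulls are built in a longitude frame chosen so the point
cloud spans < 180° where possible (so ranges straddling the antimeridian
are handled); the metrics the analyses report are ratios of areas, so the
area convention cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .occurrence import DatasetPartition

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# convex hulls on the sphere

def _best_lon_frame(lon: np.ndarray) -> tuple[np.ndarray, bool]:
    """Shift longitudes into a frame minimising their span.

    Cuts the circle at the largest angular gap between points.  Returns the
    shifted longitudes and a flag set when even the best frame spans >=180°.
    """
    u = np.unique(np.asarray(lon, float))
    if len(u) == 1:
        return np.asarray(lon, float), False
    gaps = np.diff(u)
    wrap = (u[0] + 360.0) - u[-1]
    if wrap >= gaps.max():
        cut = u[0]                  # no shift needed; span = u[-1] - u[0]
    else:
        i = int(np.argmax(gaps))
        cut = u[i + 1]              # start the frame just past the widest gap
    shifted = (np.asarray(lon, float) - cut) % 360.0 + cut
    span = shifted.max() - shifted.min()
    return shifted, bool(span >= 180.0)


def _unit_vectors(lon_deg, lat_deg) -> np.ndarray:
    lon = np.radians(np.asarray(lon_deg, float))
    lat = np.radians(np.asarray(lat_deg, float))
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


def _gc_angle(v1, v2) -> float:
    """Great-circle angle between unit vectors (numerically stable)."""
    return math.atan2(np.linalg.norm(np.cross(v1, v2)), float(np.dot(v1, v2)))


def spherical_polygon_area(lon_deg, lat_deg,
                           radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area (km²) of the spherical polygon with the given vertex cycle.

    Fan-triangulates from the first vertex and sums l'Huilier spherical
    excesses; exact for convex vertex cycles.
    """
    v = _unit_vectors(lon_deg, lat_deg)
    if len(v) < 3:
        return 0.0
    total = 0.0
    for i in range(1, len(v) - 1):
        a = _gc_angle(v[0], v[i])
        b = _gc_angle(v[i], v[i + 1])
        c = _gc_angle(v[i + 1], v[0])
        s = 0.5 * (a + b + c)
        t = (math.tan(s / 2) * math.tan((s - a) / 2)
             * math.tan((s - b) / 2) * math.tan((s - c) / 2))
        total += 4.0 * math.atan(math.sqrt(max(t, 0.0)))
    return total * radius_km ** 2


@dataclass(frozen=True)
class HullRange:
    """Convex-hull geographic range of one point set."""

    vertices: np.ndarray           # (k, 2) lon/lat, original frame
    area_km2: float
    n_points: int
    degenerate: bool = False       # < 3 distinct / collinear points
    wide_span: bool = False        # spans >=180° in every longitude frame


def hull_range(lon, lat) -> HullRange:
    """Spherical convex hull of palaeocoordinates with area in km².

    The hull is intrinsic to the sphere: points are gnomonically projected
    onto the tangent plane at their vector mean (great circles map to
    straight lines under this projection, so the planar hull *is* the
    spherical convex hull), giving hulls that are monotone under point-set
    containment and indifferent to the antimeridian.  Fewer than three
    distinct (or collinear) points give area 0.  Point clouds not contained
    in an open hemisphere have no convex hull on the sphere; they are
    flagged ``wide_span`` and measured with a longitude-frame planar hull
    as a fallback (a warning condition, not an error).
    """
    pts = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
    pts = pts[~np.isnan(pts).any(axis=1)]
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return HullRange(vertices=uniq, area_km2=0.0, n_points=len(pts),
                         degenerate=True)
    v = _unit_vectors(uniq[:, 0], uniq[:, 1])
    centre = v.mean(axis=0)
    norm = np.linalg.norm(centre)
    wide = norm < 1e-12 or (v @ (centre / max(norm, 1e-300))).min() <= 1e-9
    if wide:
        slon, _ = _best_lon_frame(uniq[:, 0])
        frame = np.column_stack([slon, uniq[:, 1]])
    else:
        centre = centre / norm
        # tangent-plane basis orthogonal to the projection centre
        pole = np.array([0.0, 0.0, 1.0]) if abs(centre[2]) < 0.9 \
            else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(pole, centre)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(centre, e1)
        depth = v @ centre
        frame = np.column_stack([(v @ e1) / depth, (v @ e2) / depth])
    try:
        hull = ConvexHull(frame)
    except QhullError:   # collinear
        return HullRange(vertices=uniq, area_km2=0.0, n_points=len(pts),
                         degenerate=True, wide_span=wide)
    cycle = hull.vertices
    area = spherical_polygon_area(uniq[cycle, 0], uniq[cycle, 1])
    return HullRange(vertices=uniq[cycle], area_km2=float(area),
                     n_points=len(pts), wide_span=wide)


def hull_area(df: pd.DataFrame) -> float:
    """Spherical hull area of a table's palaeocoordinates."""
    return hull_range(df["plon"], df["plat"]).area_km2


# ---------------------------------------------------------------------------
# occupancy

@dataclass
class GridOccupancy:
    """Occupied grid cells per dataset, with unique-contribution splits."""

    resolution: float
    cells: dict[str, set] = field(default_factory=dict)
    n_missing_coords: dict[str, int] = field(default_factory=dict)
    per_bin: pd.DataFrame | None = None

    @property
    def unique_dark(self) -> set:
        return self.cells["A"] - self.cells["B"]

    @property
    def unique_published(self) -> set:
        return self.cells["B"] - self.cells["A"]

    @property
    def shared(self) -> set:
        return self.cells["A"] & self.cells["B"]

    def summary(self) -> pd.DataFrame:
        nd = len(self.cells["D"])
        rows = [{"dataset": k, "n_cells": len(v),
                 "pct_of_total": 100.0 * len(v) / nd if nd else np.nan}
                for k, v in self.cells.items()]
        return pd.DataFrame(rows)


def _cell_set(df: pd.DataFrame, res: float) -> tuple[set, int]:
    ok = df.dropna(subset=["plon", "plat"])
    lon = ((ok["plon"].to_numpy(float) + 180.0) % 360.0) - 180.0
    ix = np.floor(lon / res).astype(int)
    iy = np.floor(ok["plat"].to_numpy(float) / res).astype(int)
    return set(zip(ix.tolist(), iy.tolist())), len(df) - len(ok)


def occupancy(part: DatasetPartition, resolution: float = 1.0,
              bin_col: str | None = None) -> GridOccupancy:
    """Grid-cell occupancy at ``resolution`` degrees for each dataset.

    Cells are indexed by the floor of coordinates over the resolution
    (labelled by their SW corner).  With ``bin_col`` set, per-bin occupied
    and uniquely-contributed cell counts — including the dark:published
    unique-cell ratio — are tabulated as well.
    """
    occ = GridOccupancy(resolution=resolution)
    for label, df in part.labelled():
        occ.cells[label], occ.n_missing_coords[label] = _cell_set(df, resolution)
    if bin_col is not None:
        rows = []
        for b in sorted(part.D[bin_col].dropna().unique()):
            sets = {label: _cell_set(df[df[bin_col] == b], resolution)[0]
                    for label, df in part.labelled()}
            ua = len(sets["A"] - sets["B"])
            ub = len(sets["B"] - sets["A"])
            rows.append({"bin": b,
                         **{f"n_cells_{k}": len(v) for k, v in sets.items()},
                         "n_unique_A": ua, "n_unique_B": ub,
                         "dark_published_unique_ratio":
                             ua / ub if ub else np.nan})
        occ.per_bin = pd.DataFrame(rows)
    return occ


# ---------------------------------------------------------------------------
# geographic range overlap / added area

def _taxon_groups(df: pd.DataFrame, rank: str, bin_col: str):
    named = df[(df[rank] != "") & df[bin_col].notna()]
    return named.groupby([rank, bin_col], sort=True, observed=True)


def range_overlap_added(part: DatasetPartition, rank: str = "genus",
                        bin_col: str = "bin") -> pd.DataFrame:
    """Per-taxon-per-bin hull-area overlap and added-area percentages.

    For each subset S of the combined dataset D:

    * ``overlap_pct``  = 100 · Area(S) / Area(D) — how much of the total
      range the subset recovers on its own;
    * ``added_pct``    = 100 · (Area(D) − Area(D∖S)) / Area(D) — how much of
      the total range would be lost without the subset.

    Taxon-bins whose total hull area is zero (point or line ranges) are
    excluded and counted in ``attrs["n_degenerate"]``.
    """
    rows = []
    n_degen = 0
    comp = {label: part.complement(label) for label, _ in part.subsets()}
    for (taxon, b), grp in _taxon_groups(part.D, rank, bin_col):
        total = hull_area(grp)
        if total <= 0.0:
            n_degen += 1
            continue
        for label, sub in part.subsets():
            s = sub[(sub[rank] == taxon) & (sub[bin_col] == b)]
            rest = comp[label]
            rest = rest[(rest[rank] == taxon) & (rest[bin_col] == b)]
            rows.append({
                "taxon": taxon, "bin": b, "dataset": label,
                "area_km2": hull_area(s) if len(s) else 0.0,
                "area_total_km2": total,
                "n_points": len(s),
                "overlap_pct": 100.0 * (hull_area(s) if len(s) else 0.0) / total,
                "added_pct": 100.0 * (total - hull_area(rest)) / total,
            })
    out = pd.DataFrame(rows)
    out.attrs["n_degenerate"] = n_degen
    return out


def summarize_ranges(ranges: pd.DataFrame,
                     value_cols=("overlap_pct", "added_pct")) -> pd.DataFrame:
    """Mean and median of range metrics across taxa, per dataset."""
    if ranges.empty:
        return pd.DataFrame()
    agg = ranges.groupby("dataset")[list(value_cols)].agg(["mean", "median"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()


# ---------------------------------------------------------------------------
# latitudinal ranges

def lat_range_metrics(part: DatasetPartition, rank: str = "genus",
                      bin_col: str = "bin") -> pd.DataFrame:
    """Latitudinal-range comparison of each subset against the total.

    Reports per taxon-bin and subset: latitudinal width, width difference
    vs the total, interval-overlap percentage, signed midpoint shift
    (positive = subset midpoint lies north of the total's), the
    occurrence-mean latitude, and the width added by the subset normalised
    both by total width and by the remaining datasets' width.
    """
    rows = []
    comp = {label: part.complement(label) for label, _ in part.subsets()}
    for (taxon, b), grp in _taxon_groups(part.D, rank, bin_col):
        lat = grp["plat"].dropna()
        if lat.empty:
            continue
        lo_d, hi_d = float(lat.min()), float(lat.max())
        width_d = hi_d - lo_d
        mid_d = 0.5 * (lo_d + hi_d)
        for label, sub in part.subsets():
            s = sub[(sub[rank] == taxon) & (sub[bin_col] == b)]["plat"].dropna()
            if s.empty:
                continue
            lo_s, hi_s = float(s.min()), float(s.max())
            width_s = hi_s - lo_s
            inter = max(0.0, min(hi_s, hi_d) - max(lo_s, lo_d))
            rest = comp[label]
            r = rest[(rest[rank] == taxon) & (rest[bin_col] == b)]["plat"].dropna()
            width_rest = float(r.max() - r.min()) if len(r) else 0.0
            rows.append({
                "taxon": taxon, "bin": b, "dataset": label,
                "lat_min": lo_s, "lat_max": hi_s,
                "width_deg": width_s,
                "width_total_deg": width_d,
                "width_diff_deg": width_d - width_s,
                "overlap_pct": (100.0 * inter / width_d) if width_d > 0
                               else 100.0,
                "midpoint_shift_deg": 0.5 * (lo_s + hi_s) - mid_d,
                "mean_lat_deg": float(s.mean()),
                "width_added_pct_total": (100.0 * (width_d - width_rest)
                                          / width_d) if width_d > 0 else 0.0,
                "width_added_pct_rest": (100.0 * (width_d - width_rest)
                                         / width_rest) if width_rest > 0
                                        else np.nan,
            })
    return pd.DataFrame(rows)
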