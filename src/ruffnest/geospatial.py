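"""Spatial covariates: distances from nests to landscape features.

All coordinates live in a planar metric frame (metres, UTM-like); the meadow
is ~km scale so no geodesic math is used.  Five covariates are produced per
nest: mean daily nearest-active-neighbour distance, distance to the nearest
lek centre active that year, and nearest-point distances to the shoreline,
the meadow edge and the path network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, MultiLineString, Point, mapping, shape

DISTANCE_COLUMNS = ("dist_nests", "dist_leks", "dist_paths", "dist_edge", "dist_shore")


@dataclass
class Lek:
    x: float
    y: float
    active_years: frozenset[int] = field(default_factory=frozenset)

    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class LandscapeFeatures:
    """Shoreline / meadow-edge polylines, path multilines and lek points."""

    shoreline: LineString
    meadow_edge: LineString
    paths: MultiLineString
    leks: list[Lek]

    def __post_init__(self) -> None:
        for name in ("shoreline", "meadow_edge"):
            geom = getattr(self, name)
            if len(geom.coords) < 2:
                raise ValueError(f"{name} polyline needs >= 2 vertices")
            if not np.all(np.isfinite(np.asarray(geom.coords))):
                raise ValueError(f"{name} has non-finite coordinates")

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson(self, path) -> None:
        features = []
        for role, geom in (("shoreline", self.shoreline),
                           ("edge", self.meadow_edge),
                           ("path", self.paths)):
            features.append({"type": "Feature",
                             "properties": {"role": role},
                             "geometry": mapping(geom)})
        for lek in self.leks:
            features.append({
                "type": "Feature",
                "properties": {"role": "lek",
                               "active_years": sorted(lek.active_years)},
                "geometry": mapping(lek.point()),
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "LandscapeFeatures":
        with open(path) as fh:
            fc = json.load(fh)
        shoreline = edge = paths = None
        leks: list[Lek] = []
        for feat in fc["features"]:
            role = feat["properties"]["role"]
            geom = shape(feat["geometry"])
            if role == "shoreline":
                shoreline = geom
            elif role == "edge":
                edge = geom
            elif role == "path":
                paths = geom if geom.geom_type == "MultiLineString" else MultiLineString([geom])
            elif role == "lek":
                leks.append(Lek(geom.x, geom.y,
                                frozenset(feat["properties"].get("active_years", []))))
        if shoreline is None or edge is None or paths is None:
            raise ValueError("GeoJSON is missing a shoreline, edge or path feature")
        return cls(shoreline, edge, paths, leks)


def point_to_polyline_distance(point, polyline) -> float:
    """Euclidean distance from a point to the nearest point on a polyline.

    The nearest point may lie in a segment interior or at a vertex.
    ``point`` is an (x, y) pair or shapely Point; ``polyline`` a LineString,
    MultiLineString, or a coordinate sequence.
    """
    if not isinstance(point, Point):
        point = Point(point)
    if not isinstance(polyline, (LineString, MultiLineString)):
        coords = list(polyline)
        if len(coords) < 2:
            raise ValueError("polyline needs at least 2 vertices")
        polyline = LineString(coords)
    if polyline.is_empty:
        raise ValueError("empty polyline")
    return float(point.distance(polyline))


def daily_nearest_neighbour_distances(focal, all_nests) -> dict[int, float]:
    """Distance to the nearest *concurrently active* other nest, per day.

    A nest is active on day d iff lay_day <= d <= end_day (closed interval).
    Days on which no other same-year nest is active are omitted.
    """
    out: dict[int, float] = {}
    neighbours = [n for n in all_nests
                  if n.nest_id != focal.nest_id and n.year == focal.year]
    if not neighbours:
        return out
    nx = np.array([n.x for n in neighbours])
    ny = np.array([n.y for n in neighbours])
    lay = np.array([n.lay_day for n in neighbours])
    end = np.array([n.end_day for n in neighbours])
    d2 = (nx - focal.x) ** 2 + (ny - focal.y) ** 2
    for day in range(focal.lay_day, focal.end_day + 1):
        active = (lay <= day) & (day <= end)
        if active.any():
            out[day] = float(np.sqrt(d2[active].min()))
    return out


def mean_daily_nearest_nest_distance(focal, all_nests) -> float | None:
    """Mean of the daily shortest nest-to-nest distances; None if no
    neighbour was ever active on a day the focal nest was."""
    daily = daily_nearest_neighbour_distances(focal, all_nests)
    if not daily:
        return None
    return float(np.mean(list(daily.values())))


def nearest_lek_distance(point, leks, year: int) -> float:
    """Distance from a point to the centre of the closest lek active in ``year``."""
    active = [l for l in leks if year in l.active_years]
    if not active:
        raise ValueError(f"no lek active in year {year}")
    px, py = (point.x, point.y) if isinstance(point, Point) else point
    d = [float(np.hypot(l.x - px, l.y - py)) for l in active]
    return min(d)


def nest_distance_table(nests, landscape: LandscapeFeatures,
                        assume_full_windows: bool = False) -> pd.DataFrame:
    """Per-nest distance covariates as a DataFrame indexed by nest_id.

    With ``assume_full_windows`` the neighbour computation treats every nest
    as active for the full capped window after laying (used by the generator,
    where fates are not yet realized).
    """
    from .records import ACTIVITY_CAP_DAYS

    if assume_full_windows:
        nests_for_nn = [n.copy(end_day=n.lay_day + ACTIVITY_CAP_DAYS) for n in nests]
    else:
        nests_for_nn = list(nests)
    by_id = {n.nest_id: n for n in nests_for_nn}

    rows = []
    for n in nests:
        p = (n.x, n.y)
        rows.append({
            "nest_id": n.nest_id,
            "year": n.year,
            "dist_nests": mean_daily_nearest_nest_distance(by_id[n.nest_id], nests_for_nn),
            "dist_leks": nearest_lek_distance(p, landscape.leks, n.year),
            "dist_paths": point_to_polyline_distance(p, landscape.paths),
            "dist_edge": point_to_polyline_distance(p, landscape.meadow_edge),
            "dist_shore": point_to_polyline_distance(p, landscape.shoreline),
        })
    return pd.DataFrame(rows).set_index("nest_id")


def predictor_correlation_matrix(table: pd.DataFrame,
                                 columns=DISTANCE_COLUMNS):
    """Pairwise Pearson correlations between distance covariates.

    Returns (r, p): symmetric DataFrames of coefficients and two-sided
    p-values, computed on pairwise-complete observations.  A zero-variance
    column yields NaN entries with a warning.
    """
    cols = [c for c in columns if c in table.columns]
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 complete pairs for {cols[i]} vs {cols[j]}")
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero variance in {cols[i]} or {cols[j]}; "
                              "correlation undefined")
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))
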