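"""Roost home ranges: filtered 100% minimum convex polygons and statistics.

A social group's roost home range is the convex hull (100% MCP — no
points discarded beyond the stated filters) of its supporting roosts.
Before hulling, roosts only ever used by a single member of the group
are removed, as are roosts more than 1 km from every other kept roost
of the group; groups left with 3 or fewer roosts are excluded because a
polygon estimate is then unreliable.  Coordinates are planar metres in
any projected CRS — no geodesic computation, which is appropriate at a
woodland-sized site; areas are reported in km².

Also provided: habitat cropping (polygon intersection), intra- and
inter-species overlap percentages, radio-fix range fidelity, the
range-area multiple regression, and the 2x2 chi-square test of whether
two species share roosts more or less than random box selection would
produce.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint, Point, mapping
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

logger = logging.getLogger("roostnet")


class DegenerateGeometryError(ValueError):
    """Fewer than 3 non-collinear points: no polygon exists."""


@dataclass
class HomeRange:
    """A social group's roost home range polygon."""

    group_id: str
    species: str
    polygon: BaseGeometry
    area_km2: float
    roost_ids: list[str] = field(default_factory=list)

    @property
    def area_m2(self) -> float:
        return self.area_km2 * 1e6


@dataclass
class GroupRoosts:
    """Filtered supporting roosts of one group, with exclusion bookkeeping."""

    group_id: str
    species: str
    roosts: pd.DataFrame           # roost_id, x, y, max_members (of this group, one date)
    excluded: bool
    reason: str | None
    removed_single_use: list[str]
    removed_isolated: list[str]


def prepare_group_roosts(
    records: pd.DataFrame,
    partition: Mapping[str, object],
    roosts: pd.DataFrame,
    isolation_km: float = 1.0,
    min_roosts: int = 4,
) -> dict[object, GroupRoosts]:
    """Per-group supporting roost sets after the MCP filters.

    A roost supports a group iff at least 2 group members were recorded
    in it on the same date.  Kept roosts more than ``isolation_km`` from
    every other kept roost of the group are then dropped (checked once,
    against the post-single-use set).  Groups with fewer than
    ``min_roosts`` remaining are flagged excluded.
    """
    coords = roosts.set_index("roost_id")[["x", "y"]]
    out: dict[object, GroupRoosts] = {}
    groups: dict[object, list[str]] = {}
    for iid, gid in partition.items():
        groups.setdefault(gid, []).append(iid)
    for gid in sorted(groups, key=str):
        members = set(groups[gid])
        sub = records[records["individual_id"].isin(members)]
        species = sub["species"].iloc[0] if len(sub) else "unknown"
        occupancy = (
            sub.groupby(["roost_id", "date"])["individual_id"].nunique().rename("n").reset_index()
        )
        per_roost = occupancy.groupby("roost_id")["n"].max()
        kept = sorted(per_roost.index[per_roost >= 2])
        single = sorted(per_roost.index[per_roost < 2])
        kept = [r for r in kept if r in coords.index]
        # isolation: > isolation_km from every *other* kept roost of the group
        removed_isolated: list[str] = []
        if len(kept) >= 2:
            pts = coords.loc[kept].to_numpy(dtype=float)
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            nearest = d.min(axis=1)
            removed_isolated = [r for r, nd in zip(kept, nearest) if nd > isolation_km * 1000.0]
            kept = [r for r in kept if r not in removed_isolated]
        excluded = len(kept) < min_roosts
        reason = None
        if excluded:
            reason = (
                "no supporting roosts after filtering" if not kept
                else f"only {len(kept)} roosts known (need >= {min_roosts})"
            )
            logger.info("group %s excluded from MCP estimation: %s", gid, reason)
        df = coords.loc[kept].reset_index() if kept else pd.DataFrame(columns=["roost_id", "x", "y"])
        if len(df):
            df["max_members"] = [int(per_roost[r]) for r in df["roost_id"]]
        out[gid] = GroupRoosts(str(gid), species, df, excluded, reason, single, removed_isolated)
    return out


def mcp(points: Sequence[tuple[float, float]] | np.ndarray,
        group_id: str = "", species: str = "",
        roost_ids: Sequence[str] = ()) -> HomeRange:
    """100% minimum convex polygon of a point set, area in km².

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or a
    collinear set (the hull is then not a polygon).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError(f"need >= 3 points for a polygon, got {len(pts)}")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise DegenerateGeometryError("points are collinear: hull is degenerate")
    return HomeRange(group_id, species, hull, hull.area / 1e6, list(roost_ids))


def ranges_from_groups(group_roosts: Mapping[object, GroupRoosts]) -> list[HomeRange]:
    """MCPs for every non-excluded group with a valid polygon."""
    out = []
    for gid, gr in group_roosts.items():
        if gr.excluded:
            continue
        try:
            out.append(
                mcp(gr.roosts[["x", "y"]].to_numpy(), str(gid), gr.species,
                    list(gr.roosts["roost_id"]))
            )
        except DegenerateGeometryError as exc:
            logger.warning("group %s: %s", gid, exc)
    return out


def crop_to_habitat(hr: HomeRange, mask: BaseGeometry) -> HomeRange:
    """Intersect a range with a habitat mask polygon (possibly multi-part)
    and recompute the area.  An empty intersection yields a zero-area
    range with a warning."""
    clipped = hr.polygon.intersection(mask)
    if clipped.is_empty:
        logger.warning("range %s lies entirely outside the habitat mask", hr.group_id)
    return HomeRange(hr.group_id, hr.species, clipped, clipped.area / 1e6, hr.roost_ids)


@dataclass
class OverlapReport:
    intra_species_pct: dict[str, float]           # union of pairwise intersections / union
    pairwise_pct: dict[str, dict[tuple[str, str], float]]
    inter_species_shared_pct_union: float | None  # shared / union of both species
    inter_species_shared_pct_by_species: dict[str, float] | None  # shared / each species' union
    max_ranges_sharing_a_point: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "intra_species_pct": self.intra_species_pct,
            "pairwise_pct": {
                sp: {f"{a}|{b}": v for (a, b), v in d_.items()} for sp, d_ in self.pairwise_pct.items()
            },
            "inter_species_shared_pct_union": self.inter_species_shared_pct_union,
            "inter_species_shared_pct_by_species": self.inter_species_shared_pct_by_species,
            "max_ranges_sharing_a_point": self.max_ranges_sharing_a_point,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _max_coverage(polys: Sequence[BaseGeometry]) -> int:
    """Maximum number of polygons covering any single point, by
    incremental overlay of (region, depth) pieces."""
    pieces: list[tuple[BaseGeometry, int]] = []
    best = 0
    for p in polys:
        if p.is_empty:
            continue
        new: list[tuple[BaseGeometry, int]] = []
        remainder = p
        for g, d in pieces:
            inter = g.intersection(p)
            if not inter.is_empty and inter.area > 0:
                new.append((inter, d + 1))
                best = max(best, d + 1)
            diff = g.difference(p)
            if not diff.is_empty and diff.area > 0:
                new.append((diff, d))
            remainder = remainder.difference(g)
        if not remainder.is_empty and remainder.area > 0:
            new.append((remainder, 1))
            best = max(best, 1)
        pieces = new
    return best


def overlap_stats(ranges: Sequence[HomeRange]) -> OverlapReport:
    """Overlap percentages within and between species.

    Intra-species overlap is union-normalised: 100 x area covered by at
    least two of the species' ranges / area covered by at least one.
    Inter-species sharing is reported both union-normalised (shared /
    union of the two species' footprints) and per species (shared / that
    species' footprint), since the denominator convention is a choice.
    """
    if len(ranges) < 2:
        raise ValueError("overlap statistics need at least 2 ranges")
    by_sp: dict[str, list[HomeRange]] = {}
    for r in ranges:
        by_sp.setdefault(r.species, []).append(r)
    intra, pairwise = {}, {}
    for sp, rs in by_sp.items():
        pairwise[sp] = {}
        if len(rs) < 2:
            intra[sp] = 0.0
            continue
        inters = []
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                inter = rs[i].polygon.intersection(rs[j].polygon)
                pairwise[sp][(rs[i].group_id, rs[j].group_id)] = (
                    100.0 * inter.area / unary_union([rs[i].polygon, rs[j].polygon]).area
                )
                if not inter.is_empty:
                    inters.append(inter)
        union = unary_union([r.polygon for r in rs])
        overlap_area = unary_union(inters).area if inters else 0.0
        intra[sp] = 100.0 * overlap_area / union.area if union.area > 0 else 0.0
    inter_union = inter_by_sp = None
    species = sorted(by_sp)
    if len(species) == 2:
        ua = unary_union([r.polygon for r in by_sp[species[0]]])
        ub = unary_union([r.polygon for r in by_sp[species[1]]])
        shared = ua.intersection(ub).area
        denom = unary_union([ua, ub]).area
        inter_union = 100.0 * shared / denom if denom > 0 else 0.0
        inter_by_sp = {
            species[0]: 100.0 * shared / ua.area if ua.area > 0 else 0.0,
            species[1]: 100.0 * shared / ub.area if ub.area > 0 else 0.0,
        }
    return OverlapReport(
        intra, pairwise, inter_union, inter_by_sp,
        _max_coverage([r.polygon for r in ranges]),
    )


def range_fidelity(fixes: pd.DataFrame, hr: HomeRange) -> dict:
    """Classify radio fixes against a range polygon.

    Returns the percentage of fixes inside (or on) the polygon and, of
    the fixes outside, the percentages within 15 m and within 100 m of
    the polygon boundary (Euclidean, planar).
    """
    if fixes.empty:
        raise ValueError("no fixes supplied")
    pts = [Point(x, y) for x, y in fixes[["x", "y"]].to_numpy(dtype=float)]
    inside = np.array([hr.polygon.covers(p) for p in pts])
    dists = np.array([0.0 if i else p.distance(hr.polygon) for i, p in zip(inside, pts)])
    n = len(pts)
    n_out = int((~inside).sum())
    out = {
        "n_fixes": n,
        "pct_inside": 100.0 * inside.sum() / n,
        "n_outside": n_out,
        "pct_outside_within_15m": (
            100.0 * float(np.sum(dists[~inside] <= 15.0)) / n_out if n_out else float("nan")
        ),
        "pct_outside_within_100m": (
            100.0 * float(np.sum(dists[~inside] <= 100.0)) / n_out if n_out else float("nan")
        ),
    }
    return out


def area_regression(
    areas: Sequence[float],
    group_sizes: Sequence[float],
    species_labels: Sequence[str],
    effort: Sequence[float],
) -> pd.DataFrame:
    """OLS of range area on group size, species, and sampling effort.

    Effort is the mean number of recaptures per individual in the group.
    Each term is tested with a marginal F: the full model against the
    model with that term removed.  Raises on rank deficiency, naming the
    collinear term.
    """
    import statsmodels.api as sm

    y = np.asarray(areas, dtype=float)
    size = np.asarray(group_sizes, dtype=float)
    eff = np.asarray(effort, dtype=float)
    sp = pd.get_dummies(pd.Series(species_labels), drop_first=True).astype(float)
    terms: dict[str, np.ndarray] = {"group_size": size}
    for c in sp.columns:
        terms[f"species[{c}]"] = sp[c].to_numpy()
    terms["effort"] = eff
    X = np.column_stack([np.ones_like(y)] + list(terms.values()))
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least 2 more observations than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # find the offending term: rank unchanged when it is dropped
        cols = list(terms)
        for i, name in enumerate(cols):
            Xr = np.delete(X, i + 1, axis=1)
            if np.linalg.matrix_rank(Xr) == np.linalg.matrix_rank(X):
                raise ValueError(f"design matrix is rank deficient: term {name!r} is collinear")
        raise ValueError("design matrix is rank deficient")
    full = sm.OLS(y, X).fit()
    rows = []
    names = ["intercept"] + list(terms)
    for i, name in enumerate(terms, start=1):
        Xr = np.delete(X, i, axis=1)
        red = sm.OLS(y, Xr).fit()
        df_num = 1
        df_den = len(y) - X.shape[1]
        if full.ssr == 0:
            F = np.inf if red.ssr > 0 else 0.0
            p = 0.0 if red.ssr > 0 else 1.0
        else:
            F = (red.ssr - full.ssr) / df_num / (full.ssr / df_den)
            p = float(stats.f.sf(F, df_num, df_den))
        rows.append({"term": name, "coef": float(full.params[i]), "F": float(F),
                     "df_num": df_num, "df_den": df_den, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["intercept"] = float(full.params[0])
    out.attrs["r_squared"] = float(full.rsquared)
    return out


def roost_sharing_test(n_species_a: int, n_species_b: int, n_shared: int, n_total_roosts: int):
    """Chi-square test of inter-species roost sharing against random use.

    Builds the 2x2 table of roost usage (used / not used by species A x
    used / not used by species B) and applies Pearson's chi-square with
    1 df (no continuity correction), expected counts from marginal
    independence.
    """
    if n_shared > min(n_species_a, n_species_b):
        raise ValueError("shared roosts cannot exceed either species' roost count")
    if max(n_species_a, n_species_b) > n_total_roosts:
        raise ValueError("species roost counts cannot exceed the total")
    neither = n_total_roosts - n_species_a - n_species_b + n_shared
    if neither < 0:
        raise ValueError("inconsistent counts: negative 'neither' cell")
    table = np.array(
        [[n_shared, n_species_a - n_shared], [n_species_b - n_shared, neither]], dtype=float
    )
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 1).any():
        logger.warning("an expected cell count is below 1: consider an exact test")
    return {"chi2": float(res.statistic), "df": 1, "p": float(res.pvalue),
            "observed_shared": n_shared,
            "expected_shared": float(res.expected_freq[0, 0])}


def ranges_to_geojson(ranges: Sequence[HomeRange], path: str | Path) -> None:
    """Write ranges as a GeoJSON FeatureCollection (planar coordinates)."""
    features = []
    for r in ranges:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.polygon),
                "properties": {
                    "group": r.group_id,
                    "species": r.species,
                    "area_km2": r.area_km2,
                    "n_roosts": len(r.roost_ids),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
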