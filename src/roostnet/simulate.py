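"""Synthetic capture-record generator with planted social structure.

Emulates the study design that produces co-roosting mark-recapture data:
several summer seasons (May 1 - Oct 15) of box checks in a woodland where
each social group cycles through its own spatial cluster of roosts, each
box is checked at most once per 14 days, detection of a present individual
is imperfect, and individuals occasionally make temporary visits to
another group's roost (the mechanism that creates the rare inter-group
associations seen in real networks).

This is a statistical-structure emulator, not a behavioural simulator: it
reproduces the sampling design (seasons, schedule, detection thinning),
the planted group/sex composition (female-core mixed groups vs >90%-male
bachelor groups), and controllable spatial separation of group roost
clusters — nothing energetic, demographic, or movement-mechanistic.

Every stochastic operation takes its RNG state from the config seed; the
same seed gives byte-identical output.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

from .records import validate_captures


@dataclass
class GroupSpec:
    """One planted social group."""

    species: str
    n_members: int
    female_fraction: float = 0.8  # female-core mixed group; 0.05 ~ bachelor
    n_roosts: int = 6


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator.

    Distances are metres; probabilities in [0, 1].  ``check_interval_days``
    is the survey cadence per group; roosts are additionally never reused
    within ``min_revisit_days`` (the box-check rule).
    """

    groups: list[GroupSpec] = field(default_factory=list)
    n_seasons: int = 5
    start_year: int = 2006
    season_start: tuple[int, int] = (5, 1)    # May 1
    season_end: tuple[int, int] = (10, 15)    # mid-October
    check_interval_days: int = 14
    min_revisit_days: int = 14
    centre_spacing: float = 600.0
    cluster_radius: float = 150.0
    survey_prob: float = 0.1
    detection_prob: float = 0.7
    mixing_prob: float = 0.01
    juvenile_fraction: float = 0.0  # default off: the analysis pools ages
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            self.groups = default_groups()
        for p, name in ((self.detection_prob, "detection_prob"),
                        (self.mixing_prob, "mixing_prob"),
                        (self.survey_prob, "survey_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups (overlap statistics are pairwise)")


def default_groups() -> list[GroupSpec]:
    """Default planted community: mixed-sex female-core groups of both
    species plus male-biased Daubenton's bachelor groups, sizes in the
    range real colonies span (a handful to a few tens of individuals)."""
    groups = []
    for i, n in enumerate([14, 11, 9, 12]):
        groups.append(GroupSpec("nattereri", n, female_fraction=0.7))
    for n in [13, 10, 12]:
        groups.append(GroupSpec("daubentonii", n, female_fraction=0.9))
    for n in [9, 8]:
        groups.append(GroupSpec("daubentonii", n, female_fraction=0.05))
    return groups


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated population."""

    group_of: dict[str, str]                 # individual -> group id
    group_centres: dict[str, tuple[float, float]]
    group_roosts: dict[str, list[str]]       # group id -> roost ids
    group_species: dict[str, str]
    sex_of: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "group_of": self.group_of,
                    "group_centres": self.group_centres,
                    "group_roosts": self.group_roosts,
                    "group_species": self.group_species,
                    "sex_of": self.sex_of,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["group_centres"] = {k: tuple(v) for k, v in d["group_centres"].items()}
        return cls(**d)


def _season_dates(config: SimulationConfig) -> list[dt.date]:
    dates = []
    for s in range(config.n_seasons):
        year = config.start_year + s
        start = dt.date(year, *config.season_start)
        end = dt.date(year, *config.season_end)
        d = start
        while d <= end:
            dates.append(d)
            d += dt.timedelta(days=config.check_interval_days)
    return dates


def _place_groups(config: SimulationConfig, rng: np.random.Generator):
    """Group centres on a square grid, roosts uniform in a disc per group.

    Grid spacing > 2 x cluster radius keeps roost clusters (hence MCPs)
    disjoint; shrinking the spacing is the overlap knob.
    """
    n = len(config.groups)
    side = math.ceil(math.sqrt(n))
    centres, roost_rows, group_roosts = {}, [], {}
    roost_counter = 0
    for g, spec in enumerate(config.groups):
        gid = f"G{g:02d}"
        cx = (g % side) * config.centre_spacing
        cy = (g // side) * config.centre_spacing
        centres[gid] = (float(cx), float(cy))
        ids = []
        for _ in range(spec.n_roosts):
            r = config.cluster_radius * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            rid = f"R{roost_counter:03d}"
            roost_counter += 1
            roost_rows.append({"roost_id": rid, "x": cx + r * math.cos(th), "y": cy + r * math.sin(th)})
            ids.append(rid)
        group_roosts[gid] = ids
    return centres, pd.DataFrame(roost_rows), group_roosts


def simulate_population(config: SimulationConfig):
    """Generate (captures, roosts, truth) with planted social groups.

    On each occasion every group occupies one roost from its own cluster
    (respecting the 14-day revisit rule); with the mixing probability an
    individual instead spends the day in a randomly chosen other group's
    roost of the same species — a temporary visit, the sole source of
    inter-group associations.  Each colony is then checked with the
    survey probability (only a fraction of boxes is visited on any day,
    as in the real sampling design), and each individual present in a
    checked colony is detected independently with the detection
    probability.

    Returns
    -------
    (captures, roosts, truth)
        captures/roosts as validated DataFrames in the records-module
        dialects; truth as :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(config.seed)
    centres, roosts, group_roosts = _place_groups(config, rng)

    # members
    group_of, sex_of, group_species, members = {}, {}, {}, {}
    counter = 0
    for g, spec in enumerate(config.groups):
        gid = f"G{g:02d}"
        group_species[gid] = spec.species
        ids = []
        n_f = int(round(spec.n_members * spec.female_fraction))
        for k in range(spec.n_members):
            iid = f"b{counter:04d}"
            counter += 1
            group_of[iid] = gid
            sex_of[iid] = "F" if k < n_f else "M"
            ids.append(iid)
        members[gid] = ids
    truth = SyntheticTruth(group_of, centres, group_roosts, group_species, sex_of)

    gids = [f"G{g:02d}" for g in range(len(config.groups))]
    same_species_others = {
        gid: [h for h in gids if h != gid and group_species[h] == group_species[gid]]
        for gid in gids
    }

    dates = _season_dates(config)
    last_used = {rid: None for rid in roosts["roost_id"]}
    rows = []
    for date in dates:
        # each group occupies one roost of its cluster, honouring min revisit
        roost_today = {}
        for gid in gids:
            avail = [
                rid
                for rid in group_roosts[gid]
                if last_used[rid] is None or (date - last_used[rid]).days >= config.min_revisit_days
            ]
            if not avail:
                avail = group_roosts[gid]
            rid = avail[rng.integers(len(avail))]
            last_used[rid] = date
            roost_today[gid] = rid
        surveyed = {gid: rng.uniform() < config.survey_prob for gid in gids}
        for gid in gids:
            spec_name = group_species[gid]
            for iid in members[gid]:
                target = gid
                others = same_species_others[gid]
                if others and rng.uniform() < config.mixing_prob:
                    target = others[rng.integers(len(others))]
                if not surveyed[target] or rng.uniform() >= config.detection_prob:
                    continue
                rows.append(
                    {
                        "individual_id": iid,
                        "species": spec_name,
                        "sex": sex_of[iid],
                        "age_class": "adult",
                        "roost_id": roost_today[target],
                        "date": date.isoformat(),
                    }
                )
    captures = validate_captures(pd.DataFrame(rows))
    return captures, roosts, truth


def simulate_tracks(
    config: SimulationConfig,
    truth: SyntheticTruth,
    roosts: pd.DataFrame,
    individual_ids: list[str],
    n_days: int = 14,
    excursion_rate: float = 0.0,
    excursion_distance: float = 50.0,
    seed: int | None = None,
):
    """Daily day-roost radio fixes for the given individuals.

    Each day an individual roosts at one of its group's roosts; with
    ``excursion_rate`` it instead roosts just outside the group's roost
    polygon, displaced ``excursion_distance`` metres beyond a hull vertex
    (so every excursion fix lies outside the hull but within that
    distance of it).
    """
    unknown = [i for i in individual_ids if i not in truth.group_of]
    if unknown:
        raise KeyError(f"unknown individuals: {unknown}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    coords = roosts.set_index("roost_id")[["x", "y"]]
    start = dt.date(config.start_year + config.n_seasons - 1, 8, 1)
    rows = []
    for iid in individual_ids:
        gid = truth.group_of[iid]
        rids = truth.group_roosts[gid]
        pts = coords.loc[rids].to_numpy(dtype=float)
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        centroid = np.asarray(hull.centroid.coords[0])
        if hull.geom_type == "Polygon":
            vertices = np.asarray(hull.exterior.coords)[:-1]
        else:  # point or line hull
            vertices = pts
        for d in range(n_days):
            date = start + dt.timedelta(days=d)
            if excursion_rate > 0 and rng.uniform() < excursion_rate:
                # push beyond a hull vertex, away from the centroid
                v = vertices[rng.integers(len(vertices))]
                direction = v - centroid
                norm = float(np.linalg.norm(direction))
                if norm < 1e-9:
                    th = rng.uniform(0, 2 * math.pi)
                    direction = np.array([math.cos(th), math.sin(th)])
                    norm = 1.0
                xy = v + direction / norm * excursion_distance
                if hull.covers(Point(xy)):  # interior vertex of a degenerate hull
                    xy = v + np.array([excursion_distance, 0.0])
            else:
                xy = pts[rng.integers(len(pts))]
            rows.append(
                {"individual_id": iid, "date": date.isoformat(), "x": float(xy[0]), "y": float(xy[1])}
            )
    fixes = pd.DataFrame(rows)
    fixes["date"] = pd.to_datetime(fixes["date"])
    return fixes
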