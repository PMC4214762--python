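"""Capture-record I/O, validation, and ring-recapture summary tables.

The atomic observation is one detection of one ringed individual at one
roost (bird box or tree cavity) on one calendar date.  A box is never
checked twice on the same day, so a "capture occasion" is a (roost, date)
pair and finer timestamps are not modelled.

Records are held as pandas DataFrames with a fixed column contract
(:data:`CAPTURE_COLUMNS`).  Loading validates the biological invariants:
sex and species are constant per individual, and duplicate
(individual, roost, date) rows — expected from field transcription — are
dropped with a warning rather than rejected.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("roostnet")

SPECIES = ("nattereri", "daubentonii")
SEXES = ("M", "F")
AGE_CLASSES = ("adult", "juvenile", "unknown")

CAPTURE_COLUMNS = ["individual_id", "species", "sex", "age_class", "roost_id", "date"]
ROOST_COLUMNS = ["roost_id", "x", "y"]
FIX_COLUMNS = ["individual_id", "date", "x", "y"]


class ValidationError(ValueError):
    """A loaded table violates a record invariant."""


#: Capture-frequency distribution from a published five-summer box-check
#: ringing study of two sympatric woodland *Myotis* species (Natterer's and
#: Daubenton's bats).  Keys are (species, sex); values map
#: times-captured -> number of individuals.  Used as a worked example and
#: as a fixed benchmark input for the summary statistics below.
MYOTIS_CAPTURE_FREQUENCIES: dict[tuple[str, str], dict[int, int]] = {
    ("daubentonii", "M"): {1: 430, 2: 118, 3: 59, 4: 14, 5: 7, 6: 0, 7: 1, 8: 0, 9: 0, 10: 0},
    ("daubentonii", "F"): {1: 204, 2: 55, 3: 33, 4: 27, 5: 13, 6: 11, 7: 4, 8: 0, 9: 2, 10: 0},
    ("nattereri", "M"): {1: 97, 2: 43, 3: 18, 4: 12, 5: 9, 6: 2, 7: 0, 8: 1, 9: 0, 10: 0},
    ("nattereri", "F"): {1: 101, 2: 71, 3: 42, 4: 40, 5: 25, 6: 14, 7: 8, 8: 7, 9: 4, 10: 3},
}


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def validate_captures(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a capture table.

    Enforces the column contract, coerces dates, checks categorical
    domains, drops verbatim duplicate (individual, roost, date) rows with
    a logged warning, and raises :class:`ValidationError` if any
    individual is recorded with more than one sex or species.
    """
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"capture table missing columns: {missing}")
    df = df[CAPTURE_COLUMNS].copy()
    for col in ("individual_id", "species", "sex", "age_class", "roost_id"):
        df[col] = df[col].astype(str).str.strip()

    bad_rows = df.index[~df["species"].isin(SPECIES)]
    if len(bad_rows):
        raise ValidationError(
            f"unknown species {df.loc[bad_rows[0], 'species']!r} at row {bad_rows[0]}"
        )
    bad_rows = df.index[~df["sex"].isin(SEXES)]
    if len(bad_rows):
        raise ValidationError(f"unknown sex {df.loc[bad_rows[0], 'sex']!r} at row {bad_rows[0]}")
    bad_rows = df.index[~df["age_class"].isin(AGE_CLASSES)]
    if len(bad_rows):
        raise ValidationError(
            f"unknown age_class {df.loc[bad_rows[0], 'age_class']!r} at row {bad_rows[0]}"
        )

    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable date in capture table: {exc}") from exc

    # sex/species must be constant per ring number
    for attr in ("sex", "species"):
        per_ind = df.groupby("individual_id")[attr].nunique()
        inconsistent = per_ind.index[per_ind > 1]
        if len(inconsistent):
            raise ValidationError(
                f"individual {inconsistent[0]!r} recorded with more than one {attr}"
            )

    n_before = len(df)
    df = df.drop_duplicates(subset=["individual_id", "roost_id", "date"]).reset_index(drop=True)
    n_dupes = n_before - len(df)
    if n_dupes:
        logger.warning("dropped %d duplicate (individual, roost, date) rows", n_dupes)
    return df


def load_captures(path: str | Path) -> pd.DataFrame:
    """Read a captures CSV (individual_id,species,sex,age_class,roost_id,date)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed captures CSV {path}: {exc}") from exc
    return validate_captures(df)


def load_roosts(path: str | Path) -> pd.DataFrame:
    """Read a roost registry CSV (roost_id,x,y) with projected planar metres."""
    df = pd.read_csv(path)
    missing = [c for c in ROOST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"roost table missing columns: {missing}")
    df = df[ROOST_COLUMNS].copy()
    df["roost_id"] = df["roost_id"].astype(str).str.strip()
    if df["roost_id"].duplicated().any():
        dup = df.loc[df["roost_id"].duplicated(), "roost_id"].iloc[0]
        raise ValidationError(f"duplicate roost_id {dup!r}")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite roost coordinates")
    df[["x", "y"]] = coords
    return df.reset_index(drop=True)


def load_fixes(path: str | Path) -> pd.DataFrame:
    """Read radio-tracking fixes CSV (individual_id,date,x,y)."""
    df = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"fixes table missing columns: {missing}")
    df = df[FIX_COLUMNS].copy()
    df["individual_id"] = df["individual_id"].astype(str).str.strip()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    df[["x", "y"]] = df[["x", "y"]].astype(float)
    return df.reset_index(drop=True)


def load_dataset(captures_path: str | Path, roosts_path: str | Path):
    """Load and cross-validate captures + roost registry.

    Roost ids in the captures that are absent from the registry are
    flagged with a warning (spatial stages will exclude them) but do not
    abort the load.
    """
    captures = load_captures(captures_path)
    roosts = load_roosts(roosts_path)
    unknown = set(captures["roost_id"]) - set(roosts["roost_id"])
    if unknown:
        logger.warning("%d roost ids in captures missing from registry: %s",
                       len(unknown), sorted(unknown)[:5])
    return captures, roosts


def write_captures(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[CAPTURE_COLUMNS].to_csv(path, index=False)


def write_roosts(df: pd.DataFrame, path: str | Path) -> None:
    df[ROOST_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def frequency_summary(counts: Mapping[int, int]) -> dict:
    """Summary statistics of a times-captured histogram.

    Parameters
    ----------
    counts
        Mapping times-captured (>=1) -> number of individuals.

    Returns
    -------
    dict with total individuals, number recaptured (caught more than
    once), proportion caught more than once, and the mean number of
    captures among individuals captured at least twice (NaN if nobody
    was recaptured).
    """
    total = int(sum(counts.values()))
    if total == 0:
        raise ValidationError("empty capture-frequency histogram")
    n_recaptured = int(sum(n for k, n in counts.items() if k >= 2))
    captures_among_recaptured = sum(k * n for k, n in counts.items() if k >= 2)
    return {
        "n_individuals": total,
        "n_recaptured": n_recaptured,
        "prop_gt_once": n_recaptured / total,
        "mean_captures_recaptured": (
            captures_among_recaptured / n_recaptured if n_recaptured else float("nan")
        ),
    }


def capture_counts(records: pd.DataFrame) -> pd.Series:
    """Number of capture occasions per individual (distinct roost-date rows)."""
    return records.groupby("individual_id").size()


def capture_frequency_table(records: pd.DataFrame) -> pd.DataFrame:
    """Frequency distribution of per-individual capture counts by stratum.

    One row per (species, sex) stratum plus an "All" row per species:
    columns ``n_1 .. n_max`` count individuals captured that many times;
    ``total`` is distinct individuals, ``prop_gt_once`` the proportion
    recaptured, and ``mean_captures_recaptured`` the mean capture count
    among the recaptured (NaN when a stratum has no recaptures).
    """
    if records.empty:
        raise ValidationError("cannot tabulate an empty record set")
    per_ind = (
        records.groupby(["species", "sex", "individual_id"]).size().rename("times").reset_index()
    )
    max_t = int(per_ind["times"].max())
    rows = []
    for species in sorted(per_ind["species"].unique()):
        sub_sp = per_ind[per_ind["species"] == species]
        strata = [(s, sub_sp[sub_sp["sex"] == s]) for s in SEXES if (sub_sp["sex"] == s).any()]
        strata.append(("All", sub_sp))
        for sex, sub in strata:
            hist = sub["times"].value_counts().to_dict()
            counts = {k: int(hist.get(k, 0)) for k in range(1, max_t + 1)}
            summ = frequency_summary(counts)
            row = {"species": species, "sex": sex}
            row.update({f"n_{k}": v for k, v in counts.items()})
            row.update(
                total=summ["n_individuals"],
                prop_gt_once=summ["prop_gt_once"],
                mean_captures_recaptured=summ["mean_captures_recaptured"],
            )
            rows.append(row)
    return pd.DataFrame(rows)


def frequency_table_from_histograms(
    histograms: Mapping[tuple[str, str], Mapping[int, int]]
) -> pd.DataFrame:
    """Build the same summary table directly from printed histograms.

    ``histograms`` maps (species, sex) -> {times_captured: count}, as in
    :data:`MYOTIS_CAPTURE_FREQUENCIES`.  Per-species "All" rows are the
    element-wise sums of the sex strata.
    """
    species_seen = sorted({sp for sp, _ in histograms})
    max_t = max(k for h in histograms.values() for k in h)
    rows = []
    for species in species_seen:
        strata: list[tuple[str, dict[int, int]]] = []
        pooled: dict[int, int] = {k: 0 for k in range(1, max_t + 1)}
        for sex in SEXES:
            h = histograms.get((species, sex))
            if h is None:
                continue
            counts = {k: int(h.get(k, 0)) for k in range(1, max_t + 1)}
            strata.append((sex, counts))
            for k, v in counts.items():
                pooled[k] += v
        strata.append(("All", pooled))
        for sex, counts in strata:
            summ = frequency_summary(counts)
            row = {"species": species, "sex": sex}
            row.update({f"n_{k}": v for k, v in counts.items()})
            row.update(
                total=summ["n_individuals"],
                prop_gt_once=summ["prop_gt_once"],
                mean_captures_recaptured=summ["mean_captures_recaptured"],
            )
            rows.append(row)
    return pd.DataFrame(rows)


def colony_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Colony sizes and per-species summaries.

    A colony is the set of individuals sharing one (roost_id, date): the
    same bats in the same box on two dates are two colonies.

    Returns
    -------
    (colonies, summary)
        ``colonies``: one row per (species, roost_id, date) with ``size``.
        ``summary``: per species median, min, max colony size and the
        number of colonies.
    """
    if records.empty:
        raise ValidationError("cannot summarise an empty record set")
    colonies = (
        records.groupby(["species", "roost_id", "date"])["individual_id"]
        .nunique()
        .rename("size")
        .reset_index()
    )
    summary = (
        colonies.groupby("species")["size"]
        .agg(n_colonies="size", median="median", min="min", max="max")
        .reset_index()
    )
    return colonies, summary
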