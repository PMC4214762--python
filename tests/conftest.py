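"""Shared fixtures: compact builders for capture-record tables."""

from __future__ import annotations

import pandas as pd
import pytest


def make_records(colonies, sexes=None, species=None, default_species="nattereri"):
    """Build a validated-shape capture table from compact colony specs.

    ``colonies``: iterable of (date_str, roost_id, [individual ids]).
    ``sexes``/``species``: optional dicts individual -> label (default F /
    ``default_species``).
    """
    sexes = sexes or {}
    species = species or {}
    rows = []
    for date, roost, ids in colonies:
        for iid in ids:
            rows.append(
                {
                    "individual_id": iid,
                    "species": species.get(iid, default_species),
                    "sex": sexes.get(iid, "F"),
                    "age_class": "adult",
                    "roost_id": roost,
                    "date": date,
                }
            )
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture
def records_builder():
    return make_records


@pytest.fixture
def five_bat_records():
    """5 bats over 3 occasions: {d1: a,b,c}, {d2: c,d}, {d3: d,e}."""
    return make_records(
        [
            ("2006-06-01", "R1", ["a", "b", "c"]),
            ("2006-06-15", "R2", ["c", "d"]),
            ("2006-07-01", "R3", ["d", "e"]),
        ]
    )
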