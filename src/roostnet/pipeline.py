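"""End-to-end orchestration of the co-roosting analysis chain.

Runs, in order: record loading (or synthetic generation) -> association
networks -> Girvan-Newman social groups -> sex-assortment and degree
tests -> lagged association rates with nulls and jackknife errors ->
roost home ranges with overlap statistics and the area regression; and
writes a single JSON report plus per-module exports.

Default analysis layout mirrors the standard design for these data:
Natterer's bats are analysed with sexes pooled (mixed-sex groups), while
Daubenton's bats are additionally split into male and female networks
(sexual segregation); spatial ranges are estimated for pooled Natterer's
groups and female Daubenton's groups.  All of this is overridable in the
config.  All seasons are pooled into one network.

Every stochastic stage draws its seed deterministically from the config
seed, so the same config and seed give an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assortment, communities, network, records, simulate, spatial, temporal

logger = logging.getLogger("roostnet")


@dataclass
class PipelineConfig:
    """Flat configuration for a full pipeline run."""

    captures_path: str | None = None
    roosts_path: str | None = None
    fixes_path: str | None = None
    habitat_mask_path: str | None = None   # GeoJSON polygon
    synthetic: bool = False
    species: tuple[str, ...] = ("nattereri", "daubentonii")
    split_sexes: tuple[str, ...] = ("daubentonii",)
    n_perm_assortment: int = 10000
    n_perm_null: int = 20
    block_days: int = 30
    lag_bins: tuple = temporal.DEFAULT_LAG_BINS
    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic:
            for p, name in ((self.captures_path, "captures_path"), (self.roosts_path, "roosts_path")):
                if p is None:
                    raise ValueError(f"{name} is required unless synthetic=true")
                if not Path(p).exists():
                    raise FileNotFoundError(p)


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse the flat ``key = value`` config format (one pair per line,
    ``#`` comments, comma-separated lists)."""
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key in ("species", "split_sexes"):
                kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
            elif key in ("n_perm_assortment", "n_perm_null", "block_days", "seed"):
                kwargs[key] = int(value)
            elif key == "synthetic":
                kwargs[key] = _BOOL[value.lower()]
            elif key in ("captures_path", "roosts_path", "fixes_path", "habitat_mask_path"):
                kwargs[key] = value
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return PipelineConfig(**kwargs)


def _stage_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not math.isfinite(obj) else float(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.date().isoformat()
    return obj


def _curve_records(df: pd.DataFrame) -> list[dict]:
    out = df.copy()
    return _jsonable(out.to_dict(orient="records"))


def _analyse_unit(G_filtered, label: str) -> tuple[communities.Partition, dict]:
    part = communities.girvan_newman(G_filtered)
    unit = {
        "label": label,
        "n_nodes": G_filtered.number_of_nodes(),
        "n_edges": G_filtered.number_of_edges(),
        "n_excluded_once_captured": G_filtered.graph.get("n_excluded_once_captured", 0),
        "n_excluded_no_associations": G_filtered.graph.get("n_excluded_no_associations", 0),
        "modularity": part.q,
        "n_groups": part.n_groups,
        "intergroup_pct": (
            communities.intergroup_fraction(G_filtered, part.assignment)
            if G_filtered.number_of_edges() else None
        ),
    }
    return part, unit


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns the report dict and writes
    ``report.json`` plus per-module exports into ``out_dir``.

    Any stage failure aborts with the stage name; a partial-results
    manifest of the stages already written is left in the output
    directory.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"seed": config.seed, "config": _jsonable(dataclasses.asdict(config))}
    stage = "load"
    try:
        # ------------------------------------------------ records
        if config.synthetic:
            sim_cfg = simulate.SimulationConfig(seed=config.seed)
            caps, roosts_df, truth = simulate.simulate_population(sim_cfg)
            truth.to_json(out_dir / "truth.json")
            records_in = caps
        else:
            records_in, roosts_df = records.load_dataset(config.captures_path, config.roosts_path)
        report["n_records"] = len(records_in)
        report["n_individuals"] = int(records_in["individual_id"].nunique())

        stage = "summary"
        freq = records.capture_frequency_table(records_in)
        freq.to_csv(out_dir / "capture_frequency.csv", index=False)
        manifest.append("capture_frequency.csv")
        colonies, colony_sum = records.colony_summary(records_in)
        report["capture_frequency"] = _jsonable(freq.to_dict(orient="records"))
        report["colony_summary"] = _jsonable(colony_sum.to_dict(orient="records"))

        # ------------------------------------------------ networks & communities
        stage = "network"
        units: dict[str, dict] = {}
        partitions: dict[str, communities.Partition] = {}
        nets: dict[str, object] = {}
        spatial_units: list[str] = []
        for sp in config.species:
            sp_records = records_in[records_in["species"] == sp]
            if sp_records.empty:
                continue
            G = network.build_network(records_in, species=sp)
            Gf = network.filter_network(G, records_in)
            nets[sp] = Gf
            part, unit = _analyse_unit(Gf, sp)
            partitions[sp] = part
            units[sp] = unit
            part.to_csv(out_dir / f"partition_{sp}.csv")
            part.trace_to_json(out_dir / f"gn_trace_{sp}.json")
            network.write_graphml(Gf, out_dir / f"network_{sp}.graphml")
            manifest += [f"partition_{sp}.csv", f"gn_trace_{sp}.json", f"network_{sp}.graphml"]
            if sp in config.split_sexes:
                for sex in ("F", "M"):
                    key = f"{sp}_{sex}"
                    Gs = network.subnetwork_by_sex(Gf, sex)
                    nets[key] = Gs
                    if Gs.number_of_edges() == 0:
                        units[key] = {"label": key, "n_nodes": Gs.number_of_nodes(), "n_edges": 0}
                        continue
                    part_s, unit_s = _analyse_unit(Gs, key)
                    partitions[key] = part_s
                    units[key] = unit_s
                    part_s.to_csv(out_dir / f"partition_{key}.csv")
                    manifest.append(f"partition_{key}.csv")
                spatial_units.append(f"{sp}_F")
            else:
                spatial_units.append(sp)
        report["networks"] = units

        # ------------------------------------------------ sex structure
        stage = "assortment"
        assort: dict[str, dict] = {}
        for i, sp in enumerate(sorted(nets)):
            G = nets[sp]
            if "_" in sp or G.number_of_edges() == 0:  # pooled-sex networks only
                continue
            sexes = {d.get("sex") for _, d in G.nodes(data=True)}
            entry: dict = {}
            jc = assortment.join_count_test(
                G, n_perm=config.n_perm_assortment, seed=_stage_seed(config.seed, 100 + i)
            )
            entry["join_count"] = _jsonable(jc.__dict__)
            if {"M", "F"} <= sexes:
                dt = assortment.degree_permutation_test(
                    G, tail="greater", n_perm=config.n_perm_assortment,
                    seed=_stage_seed(config.seed, 200 + i),
                )
                entry["degree_test"] = _jsonable(
                    {k: v for k, v in dt.__dict__.items() if k not in ("null_t", "degrees")}
                )
            assort[sp] = entry
        report["assortment"] = assort

        # ------------------------------------------------ temporal
        stage = "lar"
        lar_out: dict[str, list] = {}
        for i, sp in enumerate(config.species):
            sp_records = records_in[records_in["species"] == sp]
            if sp_records["date"].nunique() < 2:
                continue
            curves = []
            for j, (f_sex, a_sex) in enumerate([("M", "M"), ("F", "F"), ("M", "F"), ("F", "M")]):
                cur = temporal.lar_with_errors(
                    sp_records, f_sex, a_sex,
                    lag_bins=config.lag_bins, block_days=config.block_days,
                    n_perm=config.n_perm_null, seed=_stage_seed(config.seed, 300 + 10 * i + j),
                )
                curves.append(cur)
            all_curves = pd.concat(curves, ignore_index=True)
            all_curves.to_csv(out_dir / f"lar_{sp}.csv", index=False)
            manifest.append(f"lar_{sp}.csv")
            lar_out[sp] = _curve_records(all_curves)
        report["lar"] = lar_out
        report["lar_se_caveat"] = temporal.SE_CAVEAT

        # ------------------------------------------------ spatial
        stage = "spatial"
        all_ranges: list[spatial.HomeRange] = []
        range_rows = []
        spatial_report: dict = {"groups": {}}
        mask = None
        if config.habitat_mask_path:
            from shapely.geometry import shape

            with open(config.habitat_mask_path) as fh:
                gj = json.load(fh)
            geoms = (
                [shape(f["geometry"]) for f in gj["features"]]
                if gj.get("type") == "FeatureCollection" else [shape(gj)]
            )
            from shapely.ops import unary_union

            mask = unary_union(geoms)
        for key in spatial_units:
            if key not in partitions:
                continue
            sp = key.split("_")[0]
            gr = spatial.prepare_group_roosts(
                records_in[records_in["species"] == sp], partitions[key].assignment, roosts_df
            )
            ranges = spatial.ranges_from_groups(gr)
            if mask is not None:
                ranges = [spatial.crop_to_habitat(r, mask) for r in ranges]
            spatial_report["groups"][key] = {
                str(g): {
                    "excluded": v.excluded,
                    "reason": v.reason,
                    "n_roosts": len(v.roosts),
                    "removed_single_use": v.removed_single_use,
                    "removed_isolated": v.removed_isolated,
                }
                for g, v in gr.items()
            }
            counts = records.capture_counts(records_in)
            for r in ranges:
                r.group_id = f"{key}:{r.group_id}"
                members = [n for n, g in partitions[key].assignment.items()
                           if f"{key}:{g}" == r.group_id]
                eff = float(np.mean([counts.get(m, 0) - 1 for m in members])) if members else 0.0
                range_rows.append(
                    {"range_id": r.group_id, "species": r.species, "area_km2": r.area_km2,
                     "group_size": len(members), "effort": eff, "n_roosts": len(r.roost_ids)}
                )
            all_ranges.extend(ranges)
        if all_ranges:
            spatial.ranges_to_geojson(all_ranges, out_dir / "ranges.geojson")
            manifest.append("ranges.geojson")
        spatial_report["ranges"] = _jsonable(range_rows)
        if len(all_ranges) >= 2:
            rep = spatial.overlap_stats(all_ranges)
            rep.to_json(out_dir / "overlap.json")
            manifest.append("overlap.json")
            spatial_report["overlap"] = _jsonable(
                {
                    "intra_species_pct": rep.intra_species_pct,
                    "inter_species_shared_pct_union": rep.inter_species_shared_pct_union,
                    "inter_species_shared_pct_by_species": rep.inter_species_shared_pct_by_species,
                    "max_ranges_sharing_a_point": rep.max_ranges_sharing_a_point,
                }
            )
        rr = pd.DataFrame(range_rows)
        n_params = 2 + rr["species"].nunique() if len(rr) else 0
        if len(rr) >= n_params + 2 and rr["area_km2"].nunique() > 1:
            try:
                reg = spatial.area_regression(
                    rr["area_km2"], rr["group_size"], rr["species"], rr["effort"]
                )
                reg.to_csv(out_dir / "area_regression.csv", index=False)
                manifest.append("area_regression.csv")
                spatial_report["area_regression"] = _jsonable(reg.to_dict(orient="records"))
            except ValueError as exc:
                spatial_report["area_regression"] = {"skipped": str(exc)}
        report["spatial"] = spatial_report

        # fidelity, when fixes are supplied
        if config.fixes_path:
            stage = "fidelity"
            fixes = records.load_fixes(config.fixes_path)
            fid = {}
            rng_by_id = {r.group_id: r for r in all_ranges}
            for iid, sub in fixes.groupby("individual_id"):
                best = None
                for rid, r in rng_by_id.items():
                    res = spatial.range_fidelity(sub, r)
                    if best is None or res["pct_inside"] > best[1]["pct_inside"]:
                        best = (rid, res)
                if best:
                    fid[iid] = {"range": best[0], **best[1]}
            report["fidelity"] = _jsonable(fid)

        stage = "report"
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
        manifest.append("report.json")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump({"complete": True, "files": manifest}, fh, indent=1)
        return report
    except Exception:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump({"complete": False, "failed_stage": stage, "files": manifest}, fh, indent=1)
        logger.exception("pipeline aborted at stage %r", stage)
        raise
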