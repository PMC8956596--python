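"""End-to-end orchestration of the scenario analysis.

One :class:`RunConfig` (YAML or programmatic) drives the whole chain:
synthetic-world generation (optional) -> habitat accounting -> hot-spot
analysis -> fragmentation -> biodiversity loss, for every scenario, with
serialized inputs, tidy CSV outputs, and a manifest recording the config
hash, input checksums and every emitted artifact.  Identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .raster_core import (
    CategoricalGrid,
    CellAreaModel,
    ContinuousGrid,
    GridSpec,
    ZoneMap,
    aggregate_to_coarse,
    read_grid,
    write_grid,
)
from . import biodiversity_loss as bl
from . import fragmentation as frag
from . import habitat_accounting as ha
from . import hotspots as hs
from .synthetic_data import ScenarioStack, SynthConfig, SyntheticWorld, generate_world

log = logging.getLogger("urbexbio")

__all__ = ["RunConfig", "RunManifest", "run_scenario", "load_world", "write_world"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Analysis defaults mirror the study design: a 5 km buffer around
    final-epoch urban land, decadal epochs, a 1% habitat-loss threshold
    for flagging zones, the top 5% of loss cells, and 30 priority zones
    (capped at the number of zones available).
    """

    out_dir: str = "runs/demo"
    seed: int = 0
    synth: SynthConfig | None = None
    input_dir: str | None = None
    scenarios: tuple[str, ...] | None = None
    buffer_radius_m: float = 5000.0
    connectivity: int = 8
    fishnet_factor: int = 10
    fdr: bool = True
    convention: str = "ratio"
    dilution: str = "none"
    loss_threshold: float = 0.01
    top_q: float = 5.0
    k_priority: int = 30

    def __post_init__(self) -> None:
        if self.synth is None and self.input_dir is None:
            raise ValueError("config needs either a synth block or an input_dir")
        if self.convention not in ("ratio", "difference"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.dilution not in ("none", "fractional"):
            raise ValueError(f"unknown dilution {self.dilution!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synth is not None:
            sd = asdict(self.synth)
            sd["spec"] = self.synth.spec.to_json_dict()
            d["synth"] = sd
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synth"):
            sd = dict(d["synth"])
            sd["spec"] = GridSpec.from_json_dict(sd["spec"])
            if sd.get("class_proportions"):
                sd["class_proportions"] = dict(sd["class_proportions"])
            for tup in ("scenarios", "epochs", "richness_range"):
                if sd.get(tup) is not None:
                    sd[tup] = tuple(sd[tup])
            d["synth"] = SynthConfig(**sd)
        if d.get("scenarios") is not None:
            d["scenarios"] = tuple(d["scenarios"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)
    stages: dict[str, float] = field(default_factory=dict)  # wall seconds
    complete: bool = False

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# world serialization

def write_world(world: SyntheticWorld, input_dir: Path) -> list[Path]:
    """Serialize every generated input: rasters, tables, truth record."""
    input_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def _w(grid, name):
        p = write_grid(grid, input_dir / name)
        paths.append(p)

    _w(world.landcover, "landcover.tif")
    _w(world.landsystems, "landsystems.tif")
    for name, r in world.richness.items():
        _w(r, f"richness_{name}.tif")
    for zname, zm in world.zones.items():
        _w(zm.grid, f"zones_{zname}.tif")
        tp = input_dir / f"zones_{zname}.attributes.csv"
        zm.table.to_csv(tp, index=False)
        paths.append(tp)
    for sc, stack in world.stacks.items():
        for epoch, mask in zip(stack.epochs, stack.masks):
            g = CategoricalGrid(
                stack.spec, mask.astype(np.int32), {0: "nonurban", 1: "urban"}
            )
            _w(g, f"urban_{sc}_{epoch}.tif")
    cp = input_dir / "coefficients.csv"
    world.coefficients.to_csv(cp, index=False)
    paths.append(cp)
    mp = input_dir / "intensity_mapping.csv"
    world.intensity_mapping.to_csv(mp, index=False)
    paths.append(mp)
    meta = {
        "scenarios": list(world.stacks),
        "epochs": list(next(iter(world.stacks.values())).epochs),
        "coarse_factor": world.config.coarse_factor,
        "system_parent": {str(k): v for k, v in world.system_parent.items()},
        "zone_partition": {k: zm.partition for k, zm in world.zones.items()},
    }
    mp2 = input_dir / "world.json"
    mp2.write_text(json.dumps(meta, indent=1, sort_keys=True))
    paths.append(mp2)
    world.truth.to_json(input_dir / "truth.json")
    paths.append(input_dir / "truth.json")
    return paths


@dataclass
class WorldInputs:
    landcover: CategoricalGrid
    landsystems: CategoricalGrid
    richness: dict[str, ContinuousGrid]
    zones: dict[str, ZoneMap]
    stacks: dict[str, ScenarioStack]
    coefficients: pd.DataFrame
    intensity_mapping: pd.DataFrame
    coarse_factor: int


def load_world(input_dir: str | Path) -> WorldInputs:
    """Load serialized pipeline inputs (stage isolation entry point)."""
    d = Path(input_dir)
    meta = json.loads((d / "world.json").read_text())
    landcover = read_grid(d / "landcover.tif", "categorical")
    landsystems = read_grid(d / "landsystems.tif", "categorical")
    richness = {
        name: read_grid(d / f"richness_{name}.tif", "continuous")
        for name in ("all", "threatened", "small_ranged")
    }
    zones = {}
    for zp in sorted(d.glob("zones_*.tif")):
        zname = zp.stem[len("zones_") :]
        table = pd.read_csv(d / f"zones_{zname}.attributes.csv")
        zones[zname] = ZoneMap(
            zname,
            read_grid(zp, "categorical"),
            table,
            partition=meta["zone_partition"].get(zname, True),
        )
    stacks = {}
    epochs = [int(e) for e in meta["epochs"]]
    for sc in meta["scenarios"]:
        masks = [
            read_grid(d / f"urban_{sc}_{e}.tif", "categorical").codes.astype(bool)
            for e in epochs
        ]
        stacks[sc] = ScenarioStack(sc, tuple(epochs), masks, landcover.spec)
    return WorldInputs(
        landcover=landcover,
        landsystems=landsystems,
        richness=richness,
        zones=zones,
        stacks=stacks,
        coefficients=pd.read_csv(d / "coefficients.csv"),
        intensity_mapping=pd.read_csv(d / "intensity_mapping.csv"),
        coarse_factor=int(meta["coarse_factor"]),
    )


def _world_to_inputs(world: SyntheticWorld) -> WorldInputs:
    return WorldInputs(
        landcover=world.landcover,
        landsystems=world.landsystems,
        richness=world.richness,
        zones=world.zones,
        stacks=world.stacks,
        coefficients=world.coefficients,
        intensity_mapping=world.intensity_mapping,
        coarse_factor=world.config.coarse_factor,
    )


# ---------------------------------------------------------------------------
# the run

def _csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.artifacts.append(path.name)


def run_scenario(config: RunConfig) -> RunManifest:
    """Execute the full pipeline for every scenario in the config.

    Emits, under ``config.out_dir``: loss_account.csv, zone_change.csv,
    pa_overlap.csv, hotspot_summary.csv (+ z/p/gi_bin rasters),
    frag_metrics.csv, frag_medians.csv, proximity.csv,
    species_loss_by_zone.csv, species_loss_summary.csv,
    priority_zones.csv, summary.csv, manifest.json, and (synth-backed
    runs) the serialized input bundle incl. truth.json.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)

    # -- inputs -------------------------------------------------------
    t0 = time.time()
    if config.synth is not None:
        world = generate_world(config.synth)
        in_paths = write_world(world, out / "inputs")
        inputs = _world_to_inputs(world)
    else:
        in_dir = Path(config.input_dir)
        required = ["landcover.tif", "landsystems.tif", "coefficients.csv", "world.json"]
        missing = [n for n in required if not (in_dir / n).exists()]
        if missing:
            raise FileNotFoundError(f"input_dir missing required files: {missing}")
        inputs = load_world(in_dir)
        in_paths = sorted(in_dir.iterdir())
    manifest.input_checksums = {p.name: _sha256(p) for p in in_paths if p.is_file()}
    manifest.stages["inputs"] = time.time() - t0

    scenarios = list(config.scenarios or inputs.stacks)
    areas = CellAreaModel("equal_area")
    spec = inputs.landcover.spec

    # -- habitat accounting -------------------------------------------
    t0 = time.time()
    table = ha.reclass_table_from_legend(inputs.landcover.legend)
    habitat, natural = ha.reclassify(inputs.landcover, table)
    loss_frames, change_frames, pa_frames = [], [], []
    losses: dict[str, ha.PeriodLoss] = {}
    for sc in scenarios:
        log.info("habitat accounting: %s", sc)
        stack = inputs.stacks[sc]
        ploss, global_acct = ha.habitat_loss(habitat, natural, stack, areas)
        losses[sc] = ploss
        loss_frames.append(global_acct)
        for zname in ("ecoregions", "biomes", "countries"):
            if zname in inputs.zones:
                loss_frames.append(ha.zonal_loss(ploss, inputs.zones[zname], areas))
        for zname in ("priority_regions", "ecoregions"):
            if zname in inputs.zones:
                change_frames.append(
                    ha.urban_growth_by_zone(stack, inputs.zones[zname], areas)
                )
        if "protected_areas" in inputs.zones:
            pa_frames.append(
                ha.protected_overlap(stack, inputs.zones["protected_areas"], areas)
            )
    loss_account = pd.concat(loss_frames, ignore_index=True)
    _csv(loss_account, out / "loss_account.csv", manifest)
    _csv(pd.concat(change_frames, ignore_index=True), out / "zone_change.csv", manifest)
    if pa_frames:
        _csv(pd.concat(pa_frames, ignore_index=True), out / "pa_overlap.csv", manifest)
    manifest.stages["habitat_accounting"] = time.time() - t0

    # -- hot spots ----------------------------------------------------
    t0 = time.time()
    cell_area = areas.areas_km2(spec)
    hot_rows = []
    for sc in scenarios:
        log.info("hotspots: %s", sc)
        cum = losses[sc].cumulative_mask()
        field_vals = np.where(cum, cell_area, 0.0)
        field = ContinuousGrid(spec, field_vals, units="km2")
        factor = config.fishnet_factor
        if spec.n_rows % factor or spec.n_cols % factor:
            factor = 1
        res = hs.hotspot_analysis(field, fishnet_factor=factor, fdr=config.fdr)
        write_grid(res.z, out / f"hotspot_z_{sc}.tif")
        write_grid(res.p, out / f"hotspot_p_{sc}.tif")
        write_grid(res.gi_bin, out / f"hotspot_bin_{sc}.tif")
        manifest.artifacts += [
            f"hotspot_z_{sc}.tif",
            f"hotspot_p_{sc}.tif",
            f"hotspot_bin_{sc}.tif",
        ]
        bins = hs.bin_values(res.gi_bin)
        valid = np.isfinite(bins)
        hot_rows.append(
            {
                "scenario": sc,
                "band_distance_m": res.band_distance,
                "fishnet_factor": res.fishnet_factor,
                "n_cells": int(valid.sum()),
                "n_hot": int((bins[valid] > 0).sum()),
                "n_cold": int((bins[valid] < 0).sum()),
                "frac_significant": float((bins[valid] != 0).mean()),
            }
        )
    _csv(pd.DataFrame(hot_rows), out / "hotspot_summary.csv", manifest)
    manifest.stages["hotspots"] = time.time() - t0

    # -- fragmentation ------------------------------------------------
    t0 = time.time()
    frag_frames, prox_frames = [], []
    zone_for_frag = inputs.zones.get("ecoregions")
    for sc in scenarios:
        log.info("fragmentation: %s", sc)
        stack = inputs.stacks[sc]
        if zone_for_frag is not None:
            frag_frames.append(
                frag.fragmentation_in_buffer(
                    natural,
                    stack,
                    zone_for_frag,
                    radius_m=config.buffer_radius_m,
                    connectivity=config.connectivity,
                )
            )
        prox_frames.append(frag.edge_distance_series(stack, habitat, natural))
    frag_metrics = pd.concat(frag_frames, ignore_index=True)
    _csv(frag_metrics, out / "frag_metrics.csv", manifest)
    _csv(frag.median_metrics_across_zones(frag_metrics), out / "frag_medians.csv", manifest)
    _csv(pd.concat(prox_frames, ignore_index=True), out / "proximity.csv", manifest)
    manifest.stages["fragmentation"] = time.time() - t0

    # -- biodiversity loss --------------------------------------------
    t0 = time.time()
    factor = inputs.coarse_factor
    pa_coarse = None
    if "protected_areas" in inputs.zones:
        pa_frac = aggregate_to_coarse(
            inputs.zones["protected_areas"].grid, factor, "mean"
        )
        pa_mask_fine = (
            inputs.zones["protected_areas"].grid.codes
            != inputs.zones["protected_areas"].background
        )
        pa_cg = ContinuousGrid(spec, pa_mask_fine.astype(float))
        pa_coarse = aggregate_to_coarse(pa_cg, factor, "mean").values > 0
    sys_loss = bl.system_baseline_loss(inputs.intensity_mapping, inputs.coefficients)
    sys_change = bl.per_system_conversion_change(
        sys_loss, inputs.coefficients, convention=config.convention
    )
    eco = inputs.zones.get("ecoregions")
    bio_rows, zone_rows, prio_frames = [], [], []
    for sc in scenarios:
        log.info("biodiversity loss: %s", sc)
        stack = inputs.stacks[sc]
        systems2015, _ = bl.urban_overwrite(inputs.landsystems, stack.baseline)
        change = bl.relative_change_map(systems2015, stack, sys_change)
        change_ab = bl.relative_change_map(
            systems2015, stack, sys_change, which="abundance"
        )
        loss_grids, mean_change, conv_area = bl.species_loss_10km(
            change, inputs.richness, areas, factor, dilution=config.dilution
        )
        for name, g in loss_grids.items():
            write_grid(g, out / f"species_loss_{name}_{sc}.tif")
            manifest.artifacts.append(f"species_loss_{name}_{sc}.tif")
        converted = ~change.mask
        sel, coverage = (None, float("nan"))
        loss_all = loss_grids["all"]
        if np.any(loss_all.values > 0) and pa_coarse is not None:
            sel, coverage = bl.top_percentile_coverage(loss_all, config.top_q, pa_coarse)
        mc = mean_change.values[np.isfinite(mean_change.values)]
        bio_rows.append(
            {
                "scenario": sc,
                "mean_richness_change_pct": float(
                    change.values[converted].mean()
                ) if converted.any() else np.nan,
                "mean_abundance_change_pct": float(
                    change_ab.values[~change_ab.mask].mean()
                ) if converted.any() else np.nan,
                "mean_species_lost_per_cell": float(
                    loss_all.values[loss_all.values > 0].mean()
                ) if (loss_all.values > 0).any() else 0.0,
                "max_species_lost_per_cell": float(loss_all.values.max()),
                "top_pct_pa_coverage_pct": coverage,
                "converted_km2": float(conv_area.values.sum()),
            }
        )
        if eco is not None:
            eco_coarse = aggregate_to_coarse(eco.grid, factor, "mean")
            # majority zone per coarse cell via nearest integer of the mean is
            # unreliable; use the zone of the block's top-left fine cell instead
            zc = eco.grid.codes[::factor, ::factor]
            for z in eco.zone_ids():
                zsel = zc == z
                vals = loss_all.values[zsel]
                zone_rows.append(
                    {
                        "scenario": sc,
                        "zone_id": int(z),
                        "mean_species_lost": float(vals.mean()) if vals.size else 0.0,
                        "max_species_lost": float(vals.max()) if vals.size else 0.0,
                    }
                )
            # priority ranking: habitat-loss fraction + small-ranged loss
            lb = ha.zonal_loss(losses[sc], eco, areas)
            loss_by_zone = lb.groupby("zone_id")["area_km2"].sum()
            base_by_zone = ha.natural_area_by_zone(natural, eco, areas)
            with np.errstate(divide="ignore", invalid="ignore"):
                loss_frac = (loss_by_zone / base_by_zone).fillna(0.0)
            sr = loss_grids["small_ranged"].values
            sr_by_zone = pd.Series(
                {int(z): float(sr[zc == z].sum()) for z in eco.zone_ids()}
            )
            prio = bl.rank_priority_zones(
                loss_frac, sr_by_zone, min(config.k_priority, len(base_by_zone))
            )
            prio.insert(0, "scenario", sc)
            prio_frames.append(prio)
    _csv(pd.DataFrame(bio_rows), out / "species_loss_summary.csv", manifest)
    if zone_rows:
        _csv(pd.DataFrame(zone_rows), out / "species_loss_by_zone.csv", manifest)
    if prio_frames:
        _csv(pd.concat(prio_frames, ignore_index=True), out / "priority_zones.csv", manifest)
    manifest.stages["biodiversity_loss"] = time.time() - t0

    # -- cross-scenario summary ---------------------------------------
    nat_loss = (
        loss_account[loss_account["zone_system"] == "GLOBAL"]
        .groupby("scenario")["area_km2"]
        .sum()
    )
    summary = pd.DataFrame(
        {
            "scenario": nat_loss.index,
            "natural_habitat_loss_km2": nat_loss.values,
        }
    )
    _csv(summary, out / "summary.csv", manifest)

    manifest.stages["total"] = time.time() - t_start
    manifest.complete = True
    manifest.write(out / "manifest.json")
    manifest.artifacts.append("manifest.json")
    return manifest
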