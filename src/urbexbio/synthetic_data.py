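"""Synthetic study worlds with recorded ground truth.

Generates every input the pipeline needs — clustered categorical land
cover, demand-driven monotone urban expansion stacks, a land-systems map,
smooth species-richness fields (all / threatened / small-ranged), zone
systems (ecoregions, biomes, countries, protected areas, a priority
scheme), and a land-use x intensity response-coefficient table — together
with a :class:`TruthRecord` so downstream stages can be checked against
analytic oracles.

The urban allocator emulates a demand-driven cellular allocation: each
epoch, candidate non-urban cells are weighted by a smooth development
potential times ``1 + urban fraction in the 3x3 neighborhood`` and drawn
without replacement until the epoch's demand (in cells) is met.  Growth is
irreversible, so every stack is monotone by construction; because weights
never vanish, new patches may also leapfrog away from existing urban land.

Randomness is split into fixed per-product substreams of one global seed,
so regenerating one product never shifts another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.spatial import cKDTree

from .raster_core import CategoricalGrid, ContinuousGrid, GridSpec, ZoneMap

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "ScenarioStack",
    "DemandExhaustionError",
    "gen_landcover",
    "gen_urban_series",
    "gen_landsystems",
    "gen_richness",
    "gen_zones",
    "gen_coefficients",
    "gen_intensity_mapping",
    "generate_world",
]

# fixed substream keys (order is part of the reproducibility contract)
_STREAM_COVER = 11
_STREAM_POTENTIAL = 12
_STREAM_URBAN = 13
_STREAM_SYSTEMS = 14
_STREAM_RICHNESS = 15
_STREAM_ZONES = 16
_STREAM_COEFF = 17

_DEFAULT_PROPORTIONS = {
    "forest": 0.30,
    "shrubland": 0.10,
    "grassland": 0.22,
    "wetland": 0.05,
    "other": 0.08,
    "cropland": 0.22,
    "urban": 0.03,
}

#: Default total urban growth 2015->2100 per scenario, as a fraction of the
#: 2015 urban area.  The five values span the projected global range of a
#: 54-111% increase across the SSP narratives.
_DEFAULT_GROWTH = {
    "SSP1": 0.54,
    "SSP2": 0.70,
    "SSP3": 0.85,
    "SSP4": 0.95,
    "SSP5": 1.11,
}


class DemandExhaustionError(RuntimeError):
    """Urban demand exceeds the available non-urban candidate cells."""


@dataclass
class SynthConfig:
    """Parameters of a synthetic study world.

    Defaults describe a compact stand-in for the study conditions: a
    1 km working lattice, decadal epochs 2015-2100, five scenarios whose
    total urban growth spans a 54-111% increase over the 2015 urban area,
    and a landscape dominated by natural cover with ~3% initial urban land.
    """

    seed: int = 0
    spec: GridSpec = field(default_factory=lambda: GridSpec(100, 100, 1000.0))
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    clustering: float = 6.0  # mean patch diameter, cells
    scenarios: tuple[str, ...] = ("SSP1", "SSP2", "SSP3", "SSP4", "SSP5")
    epochs: tuple[int, ...] = (2015, 2020, 2030, 2040, 2050, 2060, 2070, 2080, 2090, 2100)
    demand_schedule: dict[str, list[int]] | None = None  # cells per epoch step
    potential_smoothness: float = 8.0  # correlation length, cells
    richness_range: tuple[int, int] = (50, 400)
    threatened_fraction: float = 0.12
    small_ranged_fraction: float = 0.25
    coarse_factor: int = 10  # 1 km -> 10 km nesting
    n_ecoregions: int = 12
    n_biomes: int = 4
    n_countries: int = 6
    n_protected_areas: int = 15
    pa_cover_fraction: float = 0.12
    urban_effect_pct: float = -48.0  # richness % change of urban vs baseline
    urban_abundance_pct: float = -62.0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if list(self.epochs) != sorted(set(self.epochs)):
            raise ValueError("epochs must be strictly increasing")
        self.scenarios = tuple(self.scenarios)
        self.epochs = tuple(int(e) for e in self.epochs)
        if self.demand_schedule is not None:
            for sc, sched in self.demand_schedule.items():
                if len(sched) != len(self.epochs) - 1:
                    raise ValueError(
                        f"demand schedule for {sc} needs {len(self.epochs) - 1} entries"
                    )
                if any(d < 0 for d in sched):
                    raise ValueError("demand values must be >= 0")

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *extra])

    def resolved_demand(self, n_initial_urban: int) -> dict[str, list[int]]:
        """Demand schedule in cells; defaults derive from per-scenario growth."""
        if self.demand_schedule is not None:
            return {sc: list(v) for sc, v in self.demand_schedule.items()}
        out: dict[str, list[int]] = {}
        n_steps = len(self.epochs) - 1
        growths = list(_DEFAULT_GROWTH.values())
        for i, sc in enumerate(self.scenarios):
            g = _DEFAULT_GROWTH.get(sc, growths[i % len(growths)])
            total = int(round(g * max(n_initial_urban, 1)))
            base, rem = divmod(total, n_steps)
            out[sc] = [base + (1 if k < rem else 0) for k in range(n_steps)]
        return out


@dataclass
class TruthRecord:
    """Ground truth recorded while generating a world."""

    class_cells: dict[str, int] = field(default_factory=dict)
    class_codes: dict[str, int] = field(default_factory=dict)
    urban_additions: dict[str, list[int]] = field(default_factory=dict)
    system_parent: dict[int, int] = field(default_factory=dict)
    system_change_pct: dict[int, float] = field(default_factory=dict)
    pa_cells: dict[int, int] = field(default_factory=dict)
    zone_membership: dict[str, dict[int, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _keys_to_str(d):
            return {str(k): v for k, v in d.items()}

        payload = {
            "class_cells": self.class_cells,
            "class_codes": self.class_codes,
            "urban_additions": self.urban_additions,
            "system_parent": _keys_to_str(self.system_parent),
            "system_change_pct": _keys_to_str(self.system_change_pct),
            "pa_cells": _keys_to_str(self.pa_cells),
            "zone_membership": {
                k: _keys_to_str(v) for k, v in self.zone_membership.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class ScenarioStack:
    """Ordered, monotone urban masks for one scenario.

    ``masks[0]`` is the baseline urban extent at ``epochs[0]``; conversion
    from non-urban to urban land is irreversible, so each mask is a
    superset of its predecessor.
    """

    scenario_id: str
    epochs: tuple[int, ...]
    masks: list[np.ndarray]
    spec: GridSpec

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.epochs):
            raise ValueError("one mask per epoch required")
        self.epochs = tuple(int(e) for e in self.epochs)
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        for m in self.masks:
            if m.shape != self.spec.shape:
                raise ValueError("mask shape does not match spec")
        self.validate_monotone()

    def validate_monotone(self) -> None:
        for a, b in zip(self.masks, self.masks[1:]):
            if np.any(a & ~b):
                raise ValueError(
                    f"stack {self.scenario_id} not monotone: urban cells disappear"
                )

    def mask_at(self, epoch: int) -> np.ndarray:
        return self.masks[self.epochs.index(int(epoch))]

    @property
    def baseline(self) -> np.ndarray:
        return self.masks[0]

    @property
    def final(self) -> np.ndarray:
        return self.masks[-1]

    def urban_counts(self) -> list[int]:
        return [int(m.sum()) for m in self.masks]


# ---------------------------------------------------------------------------
# land cover

def _exact_targets(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding of class proportions to exact cell counts."""
    raw = {c: p * n for c, p in proportions.items()}
    base = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda c: (raw[c] - base[c]), reverse=True)
    for c in order[:short]:
        base[c] += 1
    return base


def gen_landcover(config: SynthConfig) -> tuple[CategoricalGrid, TruthRecord]:
    """Spatially clustered categorical cover via seeded region growing.

    Class areas hit their largest-remainder targets exactly, so realized
    proportions are within rounding of the configured ones.
    """
    spec = config.spec
    rng = config.rng(_STREAM_COVER)
    n = spec.n_cells
    classes = [c for c, p in config.class_proportions.items() if p > 0]
    targets = _exact_targets(
        {c: config.class_proportions[c] for c in classes}, n
    )
    targets = {c: t for c, t in targets.items() if t > 0}
    classes = list(targets)
    if not classes:
        raise ValueError("no class has a positive cell target")

    codes = np.full(spec.shape, -1, dtype=np.int32)
    code_of = {c: i for i, c in enumerate(config.class_proportions)}
    patch_area = max(1.0, np.pi / 4.0 * config.clustering**2)
    remaining = dict(targets)
    frontiers: dict[str, list[tuple[int, int]]] = {c: [] for c in classes}
    R, C = spec.shape

    def spawn_seed(cls: str) -> None:
        free = np.flatnonzero(codes.ravel() < 0)
        if free.size == 0:
            return
        cell = int(free[rng.integers(free.size)])
        frontiers[cls].append(divmod(cell, C))

    for cls in classes:
        n_seeds = max(1, int(round(targets[cls] / patch_area)))
        for _ in range(n_seeds):
            spawn_seed(cls)

    active = [c for c in classes if remaining[c] > 0]
    while active:
        weights = np.array([remaining[c] for c in active], dtype=float)
        cls = active[rng.choice(len(active), p=weights / weights.sum())]
        front = frontiers[cls]
        if not front:
            spawn_seed(cls)
            if not frontiers[cls]:
                break  # grid full
            front = frontiers[cls]
        k = int(rng.integers(len(front)))
        front[k], front[-1] = front[-1], front[k]
        r, c = front.pop()
        if codes[r, c] >= 0:
            continue
        codes[r, c] = code_of[cls]
        remaining[cls] -= 1
        if remaining[cls] == 0:
            active = [c2 for c2 in active if c2 != cls]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < R and 0 <= cc < C and codes[rr, cc] < 0:
                front.append((rr, cc))

    # any residual unassigned cells (frontier exhaustion): fill from classes
    # that still have demand, nearest-assigned order
    free = np.argwhere(codes < 0)
    if free.size:
        still = [c for c in classes if remaining[c] > 0]
        fill = []
        for c in still:
            fill.extend([c] * remaining[c])
        rng.shuffle(fill)
        for (r, c), cls in zip(free, fill):
            codes[r, c] = code_of[cls]
            remaining[cls] -= 1

    legend = {code_of[c]: c for c in config.class_proportions}
    grid = CategoricalGrid(spec, codes, legend)
    truth = TruthRecord(
        class_cells={c: int((codes == code_of[c]).sum()) for c in config.class_proportions},
        class_codes=dict(code_of),
    )
    return grid, truth


# ---------------------------------------------------------------------------
# urban expansion

def development_potential(config: SynthConfig) -> np.ndarray:
    """Smooth positive development-potential field in (0.05, 1]."""
    rng = config.rng(_STREAM_POTENTIAL)
    raw = gaussian_filter(
        rng.standard_normal(config.spec.shape), sigma=config.potential_smoothness
    )
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.full(config.spec.shape, 1.0)
    return 0.05 + 0.95 * (raw - lo) / (hi - lo)


def gen_urban_series(
    landcover: CategoricalGrid,
    config: SynthConfig,
    scenario_id: str,
    potential: np.ndarray | None = None,
) -> tuple[ScenarioStack, TruthRecord]:
    """Demand-driven monotone urban growth for one scenario.

    Exactly ``demand[t]`` new urban cells are added at each epoch after the
    baseline, drawn without replacement with weight
    ``potential * (1 + urban fraction in the 3x3 neighborhood)``.
    """
    spec = landcover.spec
    urban_code = None
    for code, label in landcover.legend.items():
        if label == "urban":
            urban_code = code
    urban = (
        np.zeros(spec.shape, dtype=bool)
        if urban_code is None
        else landcover.codes == urban_code
    )
    if potential is None:
        potential = development_potential(config)
    demand = config.resolved_demand(int(urban.sum()))
    if scenario_id not in demand:
        raise KeyError(f"no demand schedule for scenario {scenario_id!r}")
    sched = demand[scenario_id]
    sc_index = list(config.scenarios).index(scenario_id) if scenario_id in config.scenarios else 0
    rng = config.rng(_STREAM_URBAN, sc_index)

    masks = [urban.copy()]
    additions: list[int] = []
    for d in sched:
        cand = np.flatnonzero(~urban.ravel())
        if d > cand.size:
            raise DemandExhaustionError(
                f"{scenario_id}: demand {d} exceeds {cand.size} candidate cells"
            )
        if d > 0:
            neigh = uniform_filter(urban.astype(np.float64), size=3, mode="constant")
            w = (potential * (1.0 + neigh)).ravel()[cand]
            chosen = rng.choice(cand.size, size=d, replace=False, p=w / w.sum())
            flat = urban.ravel()
            flat[cand[chosen]] = True
            urban = flat.reshape(spec.shape)
        masks.append(urban.copy())
        additions.append(int(d))

    stack = ScenarioStack(scenario_id, config.epochs, masks, spec)
    truth = TruthRecord(urban_additions={scenario_id: additions})
    return stack, truth


# ---------------------------------------------------------------------------
# land systems

_VARIANTS = ("dense", "open", "mosaic")


def gen_landsystems(
    landcover: CategoricalGrid, config: SynthConfig
) -> tuple[CategoricalGrid, dict[int, int]]:
    """Split each cover class into 1-3 land systems by a seeded smooth field.

    Returns the land-systems grid and a ``system_code -> parent cover
    code`` map; legend labels read like "dense forest" / "open forest".
    Urban cover maps to the single system "urban".
    """
    rng = config.rng(_STREAM_SYSTEMS)
    fieldv = gaussian_filter(
        rng.standard_normal(landcover.spec.shape), sigma=max(2.0, config.clustering / 2)
    )
    sys_codes = np.full(landcover.spec.shape, -1, dtype=np.int32)
    legend: dict[int, str] = {}
    parent: dict[int, int] = {}
    next_code = 0
    for code in sorted(landcover.legend):
        label = landcover.legend[code]
        cells = landcover.codes == code
        if label == "urban":
            n_sub = 1
        else:
            n_sub = int(rng.integers(1, 4))
        if not cells.any():
            # keep legend entry for the class anyway, single system
            n_sub = 1
        if n_sub == 1:
            legend[next_code] = label if label == "urban" else f"{_VARIANTS[0]} {label}"
            parent[next_code] = code
            sys_codes[cells] = next_code
            next_code += 1
            continue
        vals = fieldv[cells]
        qs = np.quantile(vals, np.linspace(0, 1, n_sub + 1)[1:-1])
        bins = np.digitize(vals, qs)
        target = np.flatnonzero(cells.ravel())
        for b in range(n_sub):
            legend[next_code] = f"{_VARIANTS[b]} {label}"
            parent[next_code] = code
            sel = target[bins == b]
            sys_codes.ravel()[sel] = next_code
            next_code += 1
    grid = CategoricalGrid(landcover.spec, sys_codes, legend)
    return grid, parent


# ---------------------------------------------------------------------------
# richness

def gen_richness(config: SynthConfig) -> dict[str, ContinuousGrid]:
    """Smooth integer richness fields on the coarse (10 km) grid.

    Returns layers ``all``, ``threatened`` and ``small_ranged``; the latter
    two are configured fractions of the total, so the containment
    invariants threatened <= all and small_ranged <= all hold by
    construction.
    """
    f = config.coarse_factor
    spec = config.spec
    if spec.n_rows % f or spec.n_cols % f:
        raise ValueError(f"coarse factor {f} does not divide {spec.shape}")
    coarse = spec.coarsen(f)
    rng = config.rng(_STREAM_RICHNESS)
    raw = gaussian_filter(rng.standard_normal(coarse.shape), sigma=2.0)
    lo, hi = raw.min(), raw.max()
    rmin, rmax = config.richness_range
    if hi - lo < 1e-12 or rmin == rmax:
        total = np.full(coarse.shape, float(rmin))
    else:
        total = rmin + (rmax - rmin) * (raw - lo) / (hi - lo)
    total = np.round(total)
    layers = {
        "all": total,
        "threatened": np.floor(total * config.threatened_fraction),
        "small_ranged": np.floor(total * config.small_ranged_fraction),
    }
    return {
        name: ContinuousGrid(coarse, vals, units="species")
        for name, vals in layers.items()
    }


# ---------------------------------------------------------------------------
# zones

def _voronoi_zones(
    spec: GridSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    rows = rng.uniform(0, spec.n_rows, n)
    cols = rng.uniform(0, spec.n_cols, n)
    tree = cKDTree(np.column_stack([rows, cols]))
    rr, cc = np.mgrid[0 : spec.n_rows, 0 : spec.n_cols]
    pts = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    _, idx = tree.query(pts)
    return (idx + 1).astype(np.int32).reshape(spec.shape)


def _grow_blobs(
    spec: GridSpec, budgets: list[int], rng: np.random.Generator
) -> np.ndarray:
    """Grow disjoint blobs with exact per-blob cell budgets (ids 1..n)."""
    R, C = spec.shape
    out = np.zeros(spec.shape, dtype=np.int32)
    order = list(range(len(budgets)))
    rng.shuffle(order)
    for bi in order:
        budget = budgets[bi]
        if budget <= 0:
            continue
        free = np.flatnonzero(out.ravel() == 0)
        if free.size == 0:
            break
        seed = int(free[rng.integers(free.size)])
        front = [divmod(seed, C)]
        placed = 0
        while front and placed < budget:
            k = int(rng.integers(len(front)))
            front[k], front[-1] = front[-1], front[k]
            r, c = front.pop()
            if out[r, c] != 0:
                continue
            out[r, c] = bi + 1
            placed += 1
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr2, cc2 = r + dr, c + dc
                if 0 <= rr2 < R and 0 <= cc2 < C and out[rr2, cc2] == 0:
                    front.append((rr2, cc2))
        # frontier exhausted early: restart from a fresh free cell
        while placed < budget:
            free = np.flatnonzero(out.ravel() == 0)
            if free.size == 0:
                break
            seed = int(free[rng.integers(free.size)])
            r, c = divmod(seed, C)
            out[r, c] = bi + 1
            placed += 1
    return out


def gen_zones(config: SynthConfig) -> dict[str, ZoneMap]:
    """Zone systems: ecoregions, biomes, countries, PAs, priority regions.

    Ecoregions (and countries) are Voronoi partitions of random seeds;
    biomes group ecoregions; protected areas are disjoint blobs whose total
    area hits ``pa_cover_fraction`` exactly at cell resolution; the
    priority scheme marks a random third of the ecoregions (a Global
    200-style subset).
    """
    spec = config.spec
    rng = config.rng(_STREAM_ZONES)
    zones: dict[str, ZoneMap] = {}

    eco = _voronoi_zones(spec, config.n_ecoregions, rng)
    eco_ids = list(range(1, config.n_ecoregions + 1))
    eco_table = pd.DataFrame(
        {"zone_id": eco_ids, "name": [f"ecoregion_{i:03d}" for i in eco_ids]}
    )
    legend = {i: n for i, n in zip(eco_table.zone_id, eco_table.name)}
    zones["ecoregions"] = ZoneMap(
        "ecoregions", CategoricalGrid(spec, eco, legend), eco_table, partition=True
    )

    biome_of = rng.integers(1, config.n_biomes + 1, size=config.n_ecoregions)
    biome = biome_of[eco - 1].astype(np.int32)
    bio_ids = sorted(set(int(b) for b in biome_of))
    bio_table = pd.DataFrame(
        {"zone_id": bio_ids, "name": [f"biome_{i}" for i in bio_ids]}
    )
    zones["biomes"] = ZoneMap(
        "biomes",
        CategoricalGrid(spec, biome, {i: f"biome_{i}" for i in bio_ids}),
        bio_table,
        partition=True,
    )

    country = _voronoi_zones(spec, config.n_countries, rng)
    c_ids = list(range(1, config.n_countries + 1))
    zones["countries"] = ZoneMap(
        "countries",
        CategoricalGrid(spec, country, {i: f"country_{i}" for i in c_ids}),
        pd.DataFrame({"zone_id": c_ids, "name": [f"country_{i}" for i in c_ids]}),
        partition=True,
    )

    target = int(round(config.pa_cover_fraction * spec.n_cells))
    npa = max(1, config.n_protected_areas)
    base, rem = divmod(target, npa)
    budgets = [base + (1 if i < rem else 0) for i in range(npa)]
    pa = _grow_blobs(spec, budgets, rng)
    pa_ids = [i for i in range(1, npa + 1) if (pa == i).any()]
    legend_pa = {i: f"pa_{i:03d}" for i in pa_ids}
    legend_pa[0] = "unprotected"
    zones["protected_areas"] = ZoneMap(
        "protected_areas",
        CategoricalGrid(spec, pa, legend_pa),
        pd.DataFrame({"zone_id": pa_ids, "name": [f"pa_{i:03d}" for i in pa_ids]}),
        partition=False,
    )

    n_pri = max(1, config.n_ecoregions // 3)
    chosen = sorted(rng.choice(eco_ids, size=n_pri, replace=False).tolist())
    pri = np.where(np.isin(eco, chosen), eco, 0).astype(np.int32)
    legend_pri = {int(i): f"priority_{int(i):03d}" for i in chosen}
    legend_pri[0] = "background"
    zones["priority_regions"] = ZoneMap(
        "priority_regions",
        CategoricalGrid(spec, pri, legend_pri),
        pd.DataFrame(
            {"zone_id": chosen, "name": [f"priority_{i:03d}" for i in chosen]}
        ),
        partition=False,
    )
    return zones


# ---------------------------------------------------------------------------
# response coefficients

_INTENSITIES = ("minimal", "light", "intense")


def gen_coefficients(config: SynthConfig) -> pd.DataFrame:
    """Land-use x intensity response-coefficient table (% vs baseline).

    Effect sizes step down with intensity; the pristine baseline row is 0
    and the urban rows carry the configured urban effect.  Columns:
    land_use_class, intensity, pct_richness, pct_abundance, ci_low, ci_high.
    """
    rng = config.rng(_STREAM_COEFF)
    classes = [c for c in config.class_proportions if c != "urban"]
    rows = [
        {
            "land_use_class": "baseline",
            "intensity": "minimal",
            "pct_richness": 0.0,
            "pct_abundance": 0.0,
            "ci_low": 0.0,
            "ci_high": 0.0,
        }
    ]
    # natural classes keep mild effects; cropland markedly negative
    for cls in classes:
        if cls == "cropland":
            base = -25.0
        else:
            base = float(rng.uniform(-12.0, -2.0))
        for k, inten in enumerate(_INTENSITIES):
            pct = base * (0.5 + 0.5 * k)  # minimal, light, intense
            rows.append(
                {
                    "land_use_class": cls,
                    "intensity": inten,
                    "pct_richness": round(pct, 2),
                    "pct_abundance": round(pct * 1.3, 2),
                    "ci_low": round(pct - 8.0, 2),
                    "ci_high": round(min(pct + 8.0, 0.0), 2),
                }
            )
    for inten in _INTENSITIES:
        rows.append(
            {
                "land_use_class": "urban",
                "intensity": inten,
                "pct_richness": config.urban_effect_pct,
                "pct_abundance": config.urban_abundance_pct,
                "ci_low": config.urban_effect_pct - 11.0,
                "ci_high": config.urban_effect_pct + 14.0,
            }
        )
    return pd.DataFrame(rows)


def gen_intensity_mapping(
    systems: CategoricalGrid, parent: dict[int, int], landcover_legend: dict[int, str]
) -> pd.DataFrame:
    """Assign each land system (class, intensity) pairs by its variant.

    "dense X" is used minimally, "open X" lightly, "mosaic X" intensely;
    single-system classes get the minimal intensity.  Columns:
    land_system_code, land_use_class, intensity.
    """
    rows = []
    for code, label in sorted(systems.legend.items()):
        cover = landcover_legend[parent[code]]
        if cover == "urban":
            rows.append(
                {"land_system_code": code, "land_use_class": "urban", "intensity": "intense"}
            )
            continue
        variant = label.split()[0]
        inten = dict(zip(_VARIANTS, _INTENSITIES)).get(variant, "minimal")
        rows.append(
            {"land_system_code": code, "land_use_class": cover, "intensity": inten}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-world convenience

@dataclass
class SyntheticWorld:
    config: SynthConfig
    landcover: CategoricalGrid
    stacks: dict[str, ScenarioStack]
    landsystems: CategoricalGrid
    system_parent: dict[int, int]
    richness: dict[str, ContinuousGrid]
    zones: dict[str, ZoneMap]
    coefficients: pd.DataFrame
    intensity_mapping: pd.DataFrame
    truth: TruthRecord


def generate_world(config: SynthConfig) -> SyntheticWorld:
    """Generate every pipeline input for one configuration."""
    landcover, truth = gen_landcover(config)
    potential = development_potential(config)
    stacks: dict[str, ScenarioStack] = {}
    for sc in config.scenarios:
        stack, t2 = gen_urban_series(landcover, config, sc, potential=potential)
        stacks[sc] = stack
        truth.urban_additions.update(t2.urban_additions)
    systems, parent = gen_landsystems(landcover, config)
    truth.system_parent = dict(parent)
    richness = gen_richness(config)
    zones = gen_zones(config)
    truth.pa_cells = {
        int(z): int((zones["protected_areas"].grid.codes == z).sum())
        for z in zones["protected_areas"].zone_ids()
    }
    coeff = gen_coefficients(config)
    mapping = gen_intensity_mapping(systems, parent, landcover.legend)
    return SyntheticWorld(
        config=config,
        landcover=landcover,
        stacks=stacks,
        landsystems=systems,
        system_parent=parent,
        richness=richness,
        zones=zones,
        coefficients=coeff,
        intensity_mapping=mapping,
        truth=truth,
    )
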