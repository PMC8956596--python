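"""Natural-habitat loss accounting under urban-expansion scenarios.

Land cover is reclassified into aggregate classes (cropland, urban,
forest, shrubland, grassland, wetland, other); everything except cropland
and urban counts as natural habitat.  Future habitat loss is a static
overlay: a cell is lost in period (t0, t1] when it held natural habitat at
the baseline, was non-urban at t0 and urban at t1.  Losses are aggregated
into a tidy ledger over zone systems (biomes, ecoregions, countries,
protected areas, prioritization schemes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .raster_core import (
    CategoricalGrid,
    CellAreaModel,
    GridSpec,
    ZoneMap,
    require_aligned,
)
from .synthetic_data import ScenarioStack

__all__ = [
    "AGGREGATE_CLASSES",
    "NATURAL_CLASSES",
    "ReclassTable",
    "PeriodLoss",
    "reclassify",
    "reclass_table_from_legend",
    "habitat_loss",
    "zonal_loss",
    "natural_area_by_zone",
    "zones_exceeding",
    "urban_growth_by_zone",
    "protected_overlap",
]

AGGREGATE_CLASSES = (
    "cropland",
    "urban",
    "forest",
    "shrubland",
    "grassland",
    "wetland",
    "other",
)
NATURAL_CLASSES = tuple(c for c in AGGREGATE_CLASSES if c not in ("cropland", "urban"))
AGG_CODE = {name: i for i, name in enumerate(AGGREGATE_CLASSES)}

LOSS_COLUMNS = [
    "scenario",
    "period_start",
    "period_end",
    "zone_system",
    "zone_id",
    "habitat_class",
    "area_km2",
]


class ReclassError(ValueError):
    """Source codes cannot be mapped to aggregate classes."""


@dataclass(frozen=True)
class ReclassTable:
    """source land-cover code -> (aggregate class, is_natural).

    ``is_natural`` is derived, not stored: it is False exactly for
    cropland and urban.
    """

    mapping: Mapping[int, str]

    def __post_init__(self) -> None:
        bad = {c: a for c, a in self.mapping.items() if a not in AGGREGATE_CLASSES}
        if bad:
            raise ReclassError(f"unknown aggregate classes: {bad}")

    def aggregate_class(self, source_code: int) -> str:
        return self.mapping[source_code]

    def is_natural(self, source_code: int) -> bool:
        return self.mapping[source_code] not in ("cropland", "urban")


_LABEL_SYNONYMS = (
    ("cropland", "cropland"),
    ("crop", "cropland"),
    ("urban", "urban"),
    ("built", "urban"),
    ("forest", "forest"),
    ("tree", "forest"),
    ("wood", "forest"),
    ("shrub", "shrubland"),
    ("grass", "grassland"),
    ("herbaceous", "grassland"),
    ("savanna", "grassland"),
    ("wetland", "wetland"),
    ("flooded", "wetland"),
)


def reclass_table_from_legend(legend: Mapping[int, str]) -> ReclassTable:
    """Build a reclass table by keyword-matching legend labels.

    "mosaic grassland" -> grassland, "tree cover" -> forest, "built-up" ->
    urban, and so on; anything unmatched maps to "other" (which counts as
    natural habitat).
    """
    mapping = {}
    for code, label in legend.items():
        low = label.lower()
        for key, agg in _LABEL_SYNONYMS:
            if key in low:
                mapping[code] = agg
                break
        else:
            mapping[code] = "other"
    return ReclassTable(mapping)


def reclassify(
    landcover: CategoricalGrid, table: ReclassTable
) -> tuple[CategoricalGrid, np.ndarray]:
    """Reclassify land cover into aggregate classes + natural-habitat mask.

    Raises :class:`ReclassError` listing any source codes the table does
    not cover.  Missing (nodata) cells stay missing and are never natural.
    """
    present = np.unique(landcover.codes[~landcover.mask])
    unmapped = [int(c) for c in present if int(c) not in table.mapping]
    if unmapped:
        raise ReclassError(f"unmapped source codes: {unmapped}")

    out = np.full(landcover.spec.shape, landcover.spec.nodata, dtype=np.int32)
    natural = np.zeros(landcover.spec.shape, dtype=bool)
    for code in present:
        agg = table.aggregate_class(int(code))
        sel = landcover.codes == code
        out[sel] = AGG_CODE[agg]
        if agg not in ("cropland", "urban"):
            natural[sel] = True
    legend = {i: name for name, i in AGG_CODE.items()}
    return CategoricalGrid(landcover.spec, out, legend), natural


@dataclass
class PeriodLoss:
    """Per-period loss grids for one scenario.

    ``grids[k]`` covers period ``(periods[k][0], periods[k][1]]`` and holds
    the aggregate-class code of the habitat lost in each cell (-1 where no
    natural habitat was lost).  ``cropland_grids`` tracks cropland->urban
    conversion separately: the paper's "total area urbanized" includes it
    while natural-habitat loss does not, so both ledgers are kept.
    """

    scenario: str
    spec: GridSpec
    periods: list[tuple[int, int]]
    grids: list[np.ndarray]
    cropland_grids: list[np.ndarray] = field(default_factory=list)

    def cumulative_mask(self) -> np.ndarray:
        out = np.zeros(self.spec.shape, dtype=bool)
        for g in self.grids:
            out |= g >= 0
        return out


def habitat_loss(
    habitat: CategoricalGrid,
    natural_mask: np.ndarray,
    stack: ScenarioStack,
    areas: CellAreaModel,
) -> tuple[PeriodLoss, pd.DataFrame]:
    """Overlay urban expansion on baseline habitat; global loss ledger.

    Loss in period (t0, t1] = cells natural at baseline, non-urban at t0
    and urban at t1.  Cells already urban at the stack baseline are never
    counted.  Returns the per-period loss grids and LossAccount rows with
    zone_system/zone_id "GLOBAL".
    """
    require_aligned(habitat)
    if habitat.spec != stack.spec:
        raise ValueError("habitat grid and stack are not aligned")
    stack.validate_monotone()
    area = areas.areas_km2(habitat.spec)

    periods: list[tuple[int, int]] = []
    grids: list[np.ndarray] = []
    crop_grids: list[np.ndarray] = []
    rows = []
    crop_code = AGG_CODE["cropland"]
    for (t0, m0), (t1, m1) in zip(
        zip(stack.epochs, stack.masks), zip(stack.epochs[1:], stack.masks[1:])
    ):
        new_urban = m1 & ~m0
        lost = new_urban & natural_mask & ~habitat.mask
        g = np.where(lost, habitat.codes, -1).astype(np.int32)
        crop = np.where(new_urban & (habitat.codes == crop_code), crop_code, -1).astype(
            np.int32
        )
        periods.append((t0, t1))
        grids.append(g)
        crop_grids.append(crop)
        for cls in NATURAL_CLASSES:
            sel = g == AGG_CODE[cls]
            rows.append(
                {
                    "scenario": stack.scenario_id,
                    "period_start": t0,
                    "period_end": t1,
                    "zone_system": "GLOBAL",
                    "zone_id": "GLOBAL",
                    "habitat_class": cls,
                    "area_km2": float(area[sel].sum()),
                }
            )
    account = pd.DataFrame(rows, columns=LOSS_COLUMNS)
    loss = PeriodLoss(stack.scenario_id, habitat.spec, periods, grids, crop_grids)
    return loss, account


def zonal_loss(
    loss: PeriodLoss, zones: ZoneMap, areas: CellAreaModel
) -> pd.DataFrame:
    """Aggregate per-period loss grids over one zone system.

    For partition zone systems the per-zone rows sum exactly to the global
    ledger (integer cell counts times areas).  Overlay systems (protected
    areas) only account for their member cells.
    """
    if zones.grid.spec != loss.spec:
        raise ValueError(f"zone raster {zones.name!r} misaligned with loss grids")
    area = areas.areas_km2(loss.spec)
    zcodes = zones.grid.codes
    rows = []
    zone_ids = zones.zone_ids()
    for (t0, t1), g in zip(loss.periods, loss.grids):
        for cls in NATURAL_CLASSES:
            sel = g == AGG_CODE[cls]
            if sel.any():
                sums = {
                    int(z): float(area[sel & (zcodes == z)].sum()) for z in zone_ids
                }
            else:
                sums = {int(z): 0.0 for z in zone_ids}
            for z in zone_ids:
                rows.append(
                    {
                        "scenario": loss.scenario,
                        "period_start": t0,
                        "period_end": t1,
                        "zone_system": zones.name,
                        "zone_id": int(z),
                        "habitat_class": cls,
                        "area_km2": sums[int(z)],
                    }
                )
    return pd.DataFrame(rows, columns=LOSS_COLUMNS)


def natural_area_by_zone(
    natural_mask: np.ndarray, zones: ZoneMap, areas: CellAreaModel
) -> pd.Series:
    """Baseline natural-habitat area (km^2) per zone."""
    area = areas.areas_km2(zones.grid.spec)
    out = {}
    for z in zones.zone_ids():
        sel = (zones.grid.codes == z) & natural_mask
        out[int(z)] = float(area[sel].sum())
    return pd.Series(out, name="baseline_km2")


def zones_exceeding(
    loss_by_zone: pd.Series, baseline_by_zone: pd.Series, threshold: float
) -> tuple[list[int], float]:
    """Zones whose fractional habitat loss strictly exceeds ``threshold``.

    Zones with zero baseline habitat are excluded with a warning.  Returns
    (zone ids, fraction of evaluable zones exceeding).
    """
    zero = [int(z) for z in baseline_by_zone.index if baseline_by_zone[z] <= 0]
    if zero:
        warnings.warn(
            f"excluding {len(zero)} zones with zero baseline habitat: {zero}",
            stacklevel=2,
        )
    evaluable = [int(z) for z in baseline_by_zone.index if baseline_by_zone[z] > 0]
    exceeding = [
        z
        for z in evaluable
        if float(loss_by_zone.get(z, 0.0)) / float(baseline_by_zone[z]) > threshold
    ]
    frac = len(exceeding) / len(evaluable) if evaluable else 0.0
    return exceeding, frac


def urban_growth_by_zone(
    stack: ScenarioStack, zones: ZoneMap, areas: CellAreaModel
) -> pd.DataFrame:
    """Per-zone urban area at baseline and each epoch, with % growth.

    ``growth_pct`` is NaN (flagged undefined) for zones with no baseline
    urban area; ``affected`` marks zones containing any urban cell at the
    epoch.
    """
    if zones.grid.spec != stack.spec:
        raise ValueError("zone raster misaligned with stack")
    area = areas.areas_km2(stack.spec)
    zcodes = zones.grid.codes
    rows = []
    base = stack.baseline
    for z in zones.zone_ids():
        zsel = zcodes == z
        a0 = float(area[zsel & base].sum())
        for epoch, mask in zip(stack.epochs, stack.masks):
            at = float(area[zsel & mask].sum())
            growth = 100.0 * (at - a0) / a0 if a0 > 0 else np.nan
            rows.append(
                {
                    "scenario": stack.scenario_id,
                    "zone_system": zones.name,
                    "zone_id": int(z),
                    "epoch": epoch,
                    "urban_area_base_km2": a0,
                    "urban_area_km2": at,
                    "growth_pct": growth,
                    "growth_defined": a0 > 0,
                    "affected": at > 0,
                }
            )
    return pd.DataFrame(rows)


def protected_overlap(
    stack: ScenarioStack, pa_zones: ZoneMap, areas: CellAreaModel
) -> pd.DataFrame:
    """Urban presence inside protected areas, per epoch.

    A PA counts as affected when at least one urban cell intersects it.
    Returns per-epoch rows: number of PAs affected, fraction of PAs
    affected, and total urban area inside PAs (km^2).
    """
    if pa_zones.grid.spec != stack.spec:
        raise ValueError("PA raster misaligned with stack")
    area = areas.areas_km2(stack.spec)
    zcodes = pa_zones.grid.codes
    ids = np.array(pa_zones.zone_ids())
    n_pa = len(ids)
    inside = zcodes != pa_zones.background
    rows = []
    for epoch, mask in zip(stack.epochs, stack.masks):
        hit = np.unique(zcodes[mask & inside])
        hit = hit[hit != pa_zones.background]
        rows.append(
            {
                "scenario": stack.scenario_id,
                "epoch": epoch,
                "n_protected_areas": n_pa,
                "n_affected": int(hit.size),
                "fraction_affected": float(hit.size) / n_pa if n_pa else 0.0,
                "urban_km2_in_pa": float(area[mask & inside].sum()),
            }
        )
    return pd.DataFrame(rows)
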