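"""From urban land conversion to species-richness and abundance loss.

Each land system is matched to one or more (land-use class, intensity)
pairs of a response-coefficient table giving the % net change in local
species richness and total abundance versus an unimpacted baseline.  The
per-system mean of those coefficients, contrasted with the urban
coefficient, yields the relative biodiversity change a cell suffers when
that system converts to urban land.  Relative changes on the 1 km lattice
are then averaged (area-weighted over converted cells) within each 10 km
cell and multiplied by the cell's species richness to estimate species
lost per cell, for all / threatened / small-ranged vertebrates.

The default contrast is the ratio convention:

    change% = 100 * (V_urban - V_system) / V_system,  V_x = 1 + pct_x/100

i.e. the loss relative to the biodiversity value of the pre-conversion
system; the percentage-point difference is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import (
    CategoricalGrid,
    CellAreaModel,
    ContinuousGrid,
    ZoneMap,
)
from .synthetic_data import ScenarioStack

__all__ = [
    "CoefficientError",
    "urban_overwrite",
    "system_baseline_loss",
    "conversion_change",
    "relative_change_map",
    "species_loss_10km",
    "top_percentile_coverage",
    "rank_priority_zones",
    "urban_coefficient",
]

COEFF_COLUMNS = ("land_use_class", "intensity", "pct_richness", "pct_abundance")
UNCLASSIFIED = "unclassified"


class CoefficientError(ValueError):
    """Coefficient table or intensity mapping is incomplete."""


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in COEFF_COLUMNS if c not in table.columns]
    if missing:
        raise CoefficientError(f"coefficient table missing columns {missing}")
    if (table[["pct_richness", "pct_abundance"]] < -100).any().any():
        raise CoefficientError("percentage changes below -100 are impossible")
    if not (table["land_use_class"] == "urban").any():
        raise CoefficientError("coefficient table must include the urban class")


def urban_overwrite(
    landsystems: CategoricalGrid, urban_2015: np.ndarray
) -> tuple[CategoricalGrid, dict[int, str]]:
    """Replace the land-systems urban layer with the baseline urban mask.

    Cells urban at the baseline become the "urban" system; cells coded
    urban in the input but not urban at baseline become "unclassified"
    (excluded from conversion accounting); all other cells are unchanged.
    Returns the updated grid and its legend.
    """
    codes = landsystems.codes.copy()
    legend = dict(landsystems.legend)
    urban_codes = [c for c, l in legend.items() if l == "urban"]
    next_code = max(legend) + 1 if legend else 0
    if urban_codes:
        urban_code = urban_codes[0]
    else:
        urban_code = next_code
        legend[urban_code] = "urban"
        next_code += 1
    stale = np.isin(codes, urban_codes) & ~urban_2015
    if stale.any():
        uncl_codes = [c for c, l in legend.items() if l == UNCLASSIFIED]
        if uncl_codes:
            uncl = uncl_codes[0]
        else:
            uncl = next_code
            legend[uncl] = UNCLASSIFIED
        codes[stale] = uncl
    codes[urban_2015] = urban_code
    return CategoricalGrid(landsystems.spec, codes, legend), legend


def system_baseline_loss(
    mapping: pd.DataFrame, table: pd.DataFrame
) -> pd.DataFrame:
    """Mean % change vs the unimpacted baseline, per land system.

    ``mapping`` rows (land_system_code, land_use_class, intensity) select
    coefficient rows; the unweighted mean over a system's assigned pairs
    is that system's loss.  A missing (class, intensity) pair is a hard
    error.  Returns columns land_system_code, pct_richness, pct_abundance.
    """
    _validate_table(table)
    lut = table.set_index(["land_use_class", "intensity"])[
        ["pct_richness", "pct_abundance"]
    ]
    rows = []
    for code, grp in mapping.groupby("land_system_code"):
        vals = []
        for _, r in grp.iterrows():
            key = (r["land_use_class"], r["intensity"])
            if key not in lut.index:
                raise CoefficientError(
                    f"no coefficient for {key!r} (land system {code})"
                )
            vals.append(lut.loc[key])
        mean = pd.DataFrame(vals).mean()
        rows.append(
            {
                "land_system_code": int(code),
                "pct_richness": float(mean["pct_richness"]),
                "pct_abundance": float(mean["pct_abundance"]),
            }
        )
    return pd.DataFrame(rows)


def urban_coefficient(table: pd.DataFrame) -> tuple[float, float]:
    """Mean (richness, abundance) % change of the urban class across
    intensities."""
    _validate_table(table)
    sel = table[table["land_use_class"] == "urban"]
    return float(sel["pct_richness"].mean()), float(sel["pct_abundance"].mean())


def conversion_change(
    system_pct: float, urban_pct: float, convention: str = "ratio"
) -> float:
    """% biodiversity change of a system -> urban conversion.

    ratio (default): 100 * (V_u - V_s) / V_s with V_x = 1 + pct_x / 100 —
    the change relative to the source system's biodiversity value.
    difference: urban_pct - system_pct (percentage points).
    """
    if system_pct < -100 or urban_pct < -100:
        raise ValueError("percentage changes below -100 are impossible")
    if convention == "difference":
        return urban_pct - system_pct
    if convention != "ratio":
        raise ValueError(f"unknown convention {convention!r}")
    vs = 1.0 + system_pct / 100.0
    vu = 1.0 + urban_pct / 100.0
    if vs == 0:
        return float("nan")  # flagged undefined: source already at -100%
    return 100.0 * (vu - vs) / vs


def per_system_conversion_change(
    system_loss: pd.DataFrame,
    table: pd.DataFrame,
    convention: str = "ratio",
) -> pd.DataFrame:
    """Conversion change per land system, for richness and abundance."""
    u_rich, u_abund = urban_coefficient(table)
    rows = []
    for _, r in system_loss.iterrows():
        rows.append(
            {
                "land_system_code": int(r["land_system_code"]),
                "change_richness_pct": conversion_change(
                    r["pct_richness"], u_rich, convention
                ),
                "change_abundance_pct": conversion_change(
                    r["pct_abundance"], u_abund, convention
                ),
            }
        )
    return pd.DataFrame(rows)


def relative_change_map(
    landsystems: CategoricalGrid,
    stack: ScenarioStack,
    system_change: pd.DataFrame,
    start_epoch: int | None = None,
    end_epoch: int | None = None,
    which: str = "richness",
) -> ContinuousGrid:
    """% biodiversity change on the 1 km conversion footprint.

    The footprint is the set of cells non-urban at ``start_epoch`` and
    urban at ``end_epoch`` (defaults: first/last stack epoch); each cell
    carries its source land system's conversion change.  Cells urban at
    baseline, unclassified cells, and cells with a system missing from
    ``system_change`` are NaN (the last are flagged via a warning column
    upstream; here they simply stay outside the footprint).
    """
    if landsystems.spec != stack.spec:
        raise ValueError("land systems misaligned with stack")
    stack.validate_monotone()
    start = stack.epochs[0] if start_epoch is None else start_epoch
    end = stack.epochs[-1] if end_epoch is None else end_epoch
    footprint = ~stack.mask_at(start) & stack.mask_at(end)
    col = {"richness": "change_richness_pct", "abundance": "change_abundance_pct"}[which]
    lut = system_change.set_index("land_system_code")[col]
    excluded = {
        c for c, l in landsystems.legend.items() if l in ("urban", UNCLASSIFIED)
    }
    out = np.full(landsystems.spec.shape, np.nan)
    for code in np.unique(landsystems.codes[footprint]):
        code = int(code)
        if code in excluded or code == landsystems.spec.nodata:
            continue
        if code in lut.index:
            out[footprint & (landsystems.codes == code)] = float(lut.loc[code])
    return ContinuousGrid(landsystems.spec, out, units="%")


def species_loss_10km(
    change_map: ContinuousGrid,
    richness: dict[str, ContinuousGrid],
    areas: CellAreaModel,
    factor: int,
    dilution: str = "none",
) -> tuple[dict[str, ContinuousGrid], ContinuousGrid, ContinuousGrid]:
    """Species lost per coarse cell from the 1 km relative-change map.

    Per 10 km cell: the area-weighted mean % change over converted 1 km
    cells, times the cell's richness (``dilution="none"``); with
    ``dilution="fractional"`` the loss is additionally scaled by the
    converted-area fraction of the cell.  Cells with no conversion lose 0.

    Returns ({layer: loss grid}, mean-change grid (%), converted-area grid
    (km^2)).
    """
    if dilution not in ("none", "fractional"):
        raise ValueError(f"unknown dilution {dilution!r}")
    spec = change_map.spec
    if spec.n_rows % factor or spec.n_cols % factor:
        raise ValueError(f"factor {factor} does not nest {spec.shape}")
    coarse = spec.coarsen(factor)
    for name, r in richness.items():
        if r.spec.shape != coarse.shape:
            raise ValueError(f"richness layer {name!r} does not match coarse grid")

    area = areas.areas_km2(spec)
    converted = ~change_map.mask
    w = np.where(converted, area, 0.0)
    wx = np.where(converted, area * change_map.values, 0.0)

    def blocks(a):
        return a.reshape(
            coarse.n_rows, factor, coarse.n_cols, factor
        ).sum(axis=(1, 3))

    wsum = blocks(w)
    wxsum = blocks(wx)
    cell_area_total = blocks(area)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_change = np.where(wsum > 0, wxsum / wsum, 0.0)
    frac = np.where(cell_area_total > 0, wsum / cell_area_total, 0.0)

    losses = {}
    for name, r in richness.items():
        loss = np.abs(mean_change) / 100.0 * r.values
        if dilution == "fractional":
            loss = loss * frac
        loss = np.minimum(loss, r.values)  # loss cannot exceed richness
        loss = np.where(wsum > 0, loss, 0.0)
        losses[name] = ContinuousGrid(coarse, loss, units="species")
    return (
        losses,
        ContinuousGrid(coarse, np.where(wsum > 0, mean_change, np.nan), units="%"),
        ContinuousGrid(coarse, wsum, units="km2"),
    )


def top_percentile_coverage(
    loss: ContinuousGrid, q: float, pa_mask_coarse: np.ndarray
) -> tuple[np.ndarray, float]:
    """Top-q% loss cells and the % of them covered by protected areas.

    Selection: cells with loss >= the (100-q)th percentile of the nonzero
    losses (ties at the cutoff included).  Coverage: % of selected cells
    intersecting the PA mask.
    """
    vals = loss.values
    nonzero = vals[np.isfinite(vals) & (vals > 0)]
    if nonzero.size == 0:
        raise ValueError("all-zero loss grid: no top-percentile cells")
    cutoff = np.percentile(nonzero, 100.0 - q)
    selected = np.isfinite(vals) & (vals >= cutoff) & (vals > 0)
    n_sel = int(selected.sum())
    coverage = 100.0 * float((selected & pa_mask_coarse).sum()) / n_sel
    return selected, coverage


def rank_priority_zones(
    habitat_loss_fraction: pd.Series,
    small_ranged_loss: pd.Series,
    k: int,
) -> pd.DataFrame:
    """Rank zones by combined habitat-loss and small-ranged-species risk.

    Each criterion is ranked descending (largest value = rank 1); the
    rank sum orders the zones (ascending = highest priority), ties broken
    by zone id.  Returns the top ``k`` with their ranks.
    """
    zones = sorted(set(habitat_loss_fraction.index) | set(small_ranged_loss.index))
    h = habitat_loss_fraction.reindex(zones).fillna(0.0)
    s = small_ranged_loss.reindex(zones).fillna(0.0)
    rank_h = h.rank(ascending=False, method="min")
    rank_s = s.rank(ascending=False, method="min")
    out = pd.DataFrame(
        {
            "zone_id": zones,
            "habitat_loss_fraction": h.values,
            "small_ranged_loss": s.values,
            "rank_habitat": rank_h.values,
            "rank_small_ranged": rank_s.values,
            "rank_sum": (rank_h + rank_s).values,
        }
    ).sort_values(["rank_sum", "zone_id"], kind="mergesort")
    out["priority_rank"] = np.arange(1, len(out) + 1)
    return out.head(int(k)).reset_index(drop=True)
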