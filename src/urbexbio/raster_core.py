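"""Grid data model, alignment rules, raster I/O, and scale-change operations.

Every stage of the pipeline works on a common row-major lattice: row 0 is
the north edge, indices are 0-based, and a cell's location is its center.
All cross-module raster inputs must share the same :class:`GridSpec`; the
pipeline validates alignment and refuses to resample silently.

Rasters are stored as single-band TIFF files whose grid metadata
(dimensions, cell size, origin, CRS label, nodata sentinel) travels in a
JSON ImageDescription tag.  Categorical rasters carry a CSV sidecar
``<name>.legend.csv`` with columns ``code,label``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RasterError",
    "GridFormatError",
    "LegendError",
    "AlignmentError",
    "GridSpec",
    "CategoricalGrid",
    "ContinuousGrid",
    "CellAreaModel",
    "ZoneMap",
    "read_grid",
    "write_grid",
    "aggregate_to_coarse",
    "cell_areas",
    "require_aligned",
]


class RasterError(Exception):
    """Base error for grid handling."""


class GridFormatError(RasterError):
    """Raster file is not a single-band grid this package understands."""


class LegendError(RasterError):
    """Categorical legend is missing, unparseable, or incomplete."""


class AlignmentError(RasterError):
    """Grids that must share a GridSpec do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions (>= 1).
    cell_size
        Cell edge length in metres (> 0).
    origin
        Map coordinates (x, y) of the outer corner of cell (0, 0),
        i.e. the north-west corner of the raster.
    crs_label
        Free-text label of the coordinate reference system.  Grids are
        "aligned" only when every field, including this label, matches.
    nodata
        Integer sentinel marking missing cells in categorical rasters.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "synthetic-equal-area"
    nodata: int = 255

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def aligned_with(self, other: "GridSpec") -> bool:
        return self == other

    def coarsen(self, factor: int) -> "GridSpec":
        """Spec of the grid obtained by aggregating factor x factor blocks."""
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"factor {factor} does not divide grid shape {self.shape}"
            )
        return replace(
            self,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            cell_size=self.cell_size * factor,
        )

    def to_json_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "origin": list(self.origin),
            "crs_label": self.crs_label,
            "nodata": self.nodata,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "GridSpec":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cell_size=float(d["cell_size"]),
            origin=tuple(d["origin"]),
            crs_label=str(d["crs_label"]),
            nodata=int(d["nodata"]),
        )


@dataclass
class CategoricalGrid:
    """Integer-coded raster with a code -> class-name legend.

    Missing cells carry ``spec.nodata``; every other code must appear in
    the legend and be non-negative.
    """

    spec: GridSpec
    codes: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.spec.shape:
            raise ValueError("codes shape does not match spec")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("categorical codes must be integers")
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.codes[self.codes != self.spec.nodata])
        if present.size and present.min() < 0:
            raise ValueError("categorical codes must be non-negative")
        missing = [int(c) for c in present if int(c) not in self.legend]
        if missing:
            raise LegendError(f"codes missing from legend: {missing}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        return self.codes == self.spec.nodata

    def class_mask(self, code: int) -> np.ndarray:
        return self.codes == code

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CategoricalGrid):
            return NotImplemented
        return (
            self.spec == other.spec
            and np.array_equal(self.codes, other.codes)
            and self.legend == other.legend
        )


@dataclass
class ContinuousGrid:
    """Real-valued raster; missing cells are NaN."""

    spec: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise ValueError("values shape does not match spec")
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise ValueError("non-nodata values must be finite")

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass(frozen=True)
class CellAreaModel:
    """Per-cell area model.

    ``equal_area`` treats every cell as ``(cell_size/1000)**2`` km^2 —
    appropriate for equal-area projections and for synthetic worlds.
    ``cosine_latitude`` scales each row's area by cos(latitude), a
    light-weight stand-in for geographic grids; it requires one latitude
    (degrees) per row.
    """

    mode: str = "equal_area"
    reference_latitudes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("equal_area", "cosine_latitude"):
            raise ValueError(f"unknown area mode {self.mode!r}")
        if self.reference_latitudes is not None:
            object.__setattr__(
                self, "reference_latitudes", tuple(float(v) for v in self.reference_latitudes)
            )

    def row_areas_km2(self, spec: GridSpec) -> np.ndarray:
        """Area (km^2) of one cell in each row."""
        base = (spec.cell_size / 1000.0) ** 2
        if self.mode == "equal_area":
            return np.full(spec.n_rows, base)
        if self.reference_latitudes is None:
            raise ValueError("cosine_latitude mode requires reference_latitudes")
        lats = np.asarray(self.reference_latitudes, dtype=float)
        if lats.shape != (spec.n_rows,):
            raise ValueError("need one reference latitude per row")
        areas = base * np.cos(np.deg2rad(lats))
        if not (areas > 0).all():
            raise ValueError("cell areas must be strictly positive")
        return areas

    def areas_km2(self, spec: GridSpec) -> np.ndarray:
        return np.repeat(self.row_areas_km2(spec)[:, None], spec.n_cols, axis=1)


@dataclass
class ZoneMap:
    """Integer-coded spatial partition or overlay used for aggregation.

    ``partition`` marks zone systems that tile the full grid (ecoregions,
    biomes, countries); protected areas and priority schemes leave
    background cells coded 0.  ``table`` is the attribute table with at
    least columns ``zone_id`` and ``name``.
    """

    name: str
    grid: CategoricalGrid
    table: pd.DataFrame
    partition: bool = True
    background: int = 0

    def zone_ids(self) -> list[int]:
        return [int(z) for z in self.table["zone_id"]]


def require_aligned(*grids) -> GridSpec:
    """Check that all grids share one GridSpec and return it."""
    specs = [g.spec for g in grids]
    first = specs[0]
    for s in specs[1:]:
        if s != first:
            raise AlignmentError(f"grid specs differ: {first} vs {s}")
    return first


# ---------------------------------------------------------------------------
# I/O

def _legend_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix("").parent / (path.stem + ".legend.csv")


def write_grid(grid: CategoricalGrid | ContinuousGrid, path: str | Path) -> Path:
    """Write a grid as a single-band TIFF (+ legend sidecar if categorical).

    Integer rasters round-trip bit-exactly; floats round-trip exactly as
    float64.  The GridSpec travels in a JSON ImageDescription tag.
    """
    path = Path(path)
    meta = grid.spec.to_json_dict()
    if isinstance(grid, CategoricalGrid):
        meta["kind"] = "categorical"
        data = np.ascontiguousarray(grid.codes, dtype=np.int32)
        pd.DataFrame(
            {"code": list(grid.legend), "label": list(grid.legend.values())}
        ).to_csv(_legend_path(path), index=False)
    else:
        meta["kind"] = "continuous"
        meta["units"] = grid.units
        data = np.ascontiguousarray(grid.values, dtype=np.float64)
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def _read_legend(path: Path) -> dict[int, str]:
    lp = _legend_path(path)
    if not lp.exists():
        raise LegendError(f"legend sidecar not found: {lp}")
    try:
        df = pd.read_csv(lp)
        return {int(c): str(l) for c, l in zip(df["code"], df["label"])}
    except LegendError:
        raise
    except Exception as exc:  # malformed CSV, wrong columns...
        raise LegendError(f"unparseable legend {lp}: {exc}") from exc


def read_grid(path: str | Path, kind: str) -> CategoricalGrid | ContinuousGrid:
    """Read a grid written by :func:`write_grid`.

    Parameters
    ----------
    path : file path to a single-band TIFF
    kind : "categorical" or "continuous"
    """
    path = Path(path)
    if kind not in ("categorical", "continuous"):
        raise ValueError(f"kind must be categorical or continuous, got {kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        if len(series.shape) != 2:
            raise GridFormatError(
                f"{path}: expected single-band 2-D raster, got shape {series.shape}"
            )
        data = series.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
        spec = GridSpec.from_json_dict(meta)
    except Exception as exc:
        raise GridFormatError(f"{path}: missing or invalid grid metadata") from exc
    if kind == "categorical":
        legend = _read_legend(path)
        return CategoricalGrid(spec, data.astype(np.int32), legend)
    return ContinuousGrid(spec, data.astype(np.float64), units=meta.get("units", ""))


# ---------------------------------------------------------------------------
# Scale change

def _blocks(a: np.ndarray, factor: int) -> np.ndarray:
    r, c = a.shape
    return a.reshape(r // factor, factor, c // factor, factor).swapaxes(1, 2)


def aggregate_to_coarse(
    fine: CategoricalGrid | ContinuousGrid,
    factor: int,
    reducer: str = "sum",
    code: int | None = None,
) -> ContinuousGrid:
    """Aggregate factor x factor blocks of a fine grid into one coarse cell.

    ``reducer`` is one of ``sum``, ``mean`` or ``class_fraction`` (the
    latter needs ``code`` and a categorical input).  Missing cells are
    ignored; blocks that are entirely missing become NaN.
    """
    if fine.spec.n_rows % factor or fine.spec.n_cols % factor:
        raise ValueError(f"factor {factor} does not divide {fine.spec.shape}")
    coarse_spec = fine.spec.coarsen(factor)

    if isinstance(fine, CategoricalGrid):
        valid = ~fine.mask
        if reducer == "class_fraction":
            if code is None:
                raise ValueError("class_fraction reducer needs a code")
            values = (fine.codes == code).astype(np.float64)
        else:
            values = fine.codes.astype(np.float64)
    else:
        valid = ~fine.mask
        if reducer == "class_fraction":
            raise ValueError("class_fraction applies to categorical grids only")
        values = np.where(valid, fine.values, 0.0)
    values = np.where(valid, values, 0.0)

    bsum = _blocks(values, factor).sum(axis=(2, 3))
    bcount = _blocks(valid.astype(np.float64), factor).sum(axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        if reducer == "sum":
            out = np.where(bcount > 0, bsum, np.nan)
        elif reducer in ("mean", "class_fraction"):
            out = np.where(bcount > 0, bsum / bcount, np.nan)
        else:
            raise ValueError(f"unknown reducer {reducer!r}")
    return ContinuousGrid(coarse_spec, out)


def cell_areas(spec: GridSpec, model: CellAreaModel) -> ContinuousGrid:
    """Per-cell area grid in km^2 under the given area model."""
    return ContinuousGrid(spec, model.areas_km2(spec), units="km2")
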