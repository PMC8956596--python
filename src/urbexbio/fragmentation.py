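"""Fragmentation of natural habitat near urban land.

Two families of measures:

* Patch-structure metrics of natural habitat within a buffer (default
  5 km) around urban land, per zone (ecoregion): mean patch size (MPS,
  ha), edge density (ED, m/ha) and mean Euclidean nearest-neighbor
  distance between patches (ENN_MN, m).
* The proximity effect: the mean distance from urban patch edges to the
  nearest natural-habitat patch edges, tracked over epochs; a positive
  change (d_prev - d_curr) means urban land moved closer to habitat.

Conventions: patches are connected components (8-connectivity by
default); an edge cell is a class cell with at least one 4-neighbor of a
different class inside the analysis extent (the raster exterior never
counts as edge); distances are cell-center to cell-center Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label

from .raster_core import CategoricalGrid, GridSpec, ZoneMap
from .synthetic_data import ScenarioStack

__all__ = [
    "PatchSet",
    "label_patches",
    "edge_cells",
    "class_metrics",
    "urban_buffer",
    "fragmentation_in_buffer",
    "edge_distance_series",
]


@dataclass
class PatchSet:
    """Labeled patches of one class mask (labels 1..n_patches, 0 = background)."""

    labels: np.ndarray
    connectivity: int  # 4 or 8
    n_patches: int

    def sizes(self) -> np.ndarray:
        """Patch sizes in cells, indexed 0..n_patches-1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_patches + 1)[1:]


def label_patches(mask: np.ndarray, connectivity: int = 8) -> PatchSet:
    """Maximal connected components of a binary mask."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    labels, n = sk_label(np.asarray(mask, dtype=bool), connectivity=conn, return_num=True)
    return PatchSet(labels.astype(np.int32), connectivity, int(n))


def _four_neighbor_shifts(a: np.ndarray):
    """Pairs (neighbor view, same-shape slice) for the 4 directions,
    exterior padded as False/0."""
    out = []
    padded = np.pad(a, 1, mode="constant", constant_values=0)
    out.append(padded[:-2, 1:-1])  # up
    out.append(padded[2:, 1:-1])  # down
    out.append(padded[1:-1, :-2])  # left
    out.append(padded[1:-1, 2:])  # right
    return out


def edge_cells(class_mask: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """Class cells with >= 1 4-neighbor of different class inside the extent."""
    cm = class_mask & extent
    other = extent & ~cm
    edge = np.zeros_like(cm)
    for nb in _four_neighbor_shifts(other.astype(np.int8)):
        edge |= nb.astype(bool)
    return cm & edge


def _edge_length_m(class_mask: np.ndarray, extent: np.ndarray, cell_size: float) -> float:
    """Total length of sides shared between class and different-class cells
    inside the extent.  Exterior (and out-of-extent) sides are excluded."""
    cm = class_mask & extent
    other = (extent & ~cm).astype(np.int8)
    n_sides = 0
    for nb in _four_neighbor_shifts(other):
        n_sides += int(nb[cm].sum())
    return n_sides * cell_size


def _enn_mean_m(patches: PatchSet, extent: np.ndarray, cell_size: float) -> float:
    """Mean over patches of the distance to the nearest other patch,
    measured between edge-cell centers."""
    if patches.n_patches < 2:
        return float("nan")
    cm = patches.labels > 0
    edges = edge_cells(cm, extent)
    pts_per_patch: list[np.ndarray] = []
    for pid in range(1, patches.n_patches + 1):
        sel = edges & (patches.labels == pid)
        if not sel.any():
            sel = patches.labels == pid  # patch with no edge cells: use all
        pts_per_patch.append(np.argwhere(sel).astype(float))
    all_pts = np.vstack(pts_per_patch)
    owner = np.concatenate(
        [np.full(len(p), i) for i, p in enumerate(pts_per_patch)]
    )
    tree = cKDTree(all_pts)
    dists = []
    for i, pts in enumerate(pts_per_patch):
        # query enough neighbors to escape own patch
        k = min(len(all_pts), len(pts) + 1)
        best = np.inf
        dd, ii = tree.query(pts, k=k)
        dd = np.atleast_2d(dd)
        ii = np.atleast_2d(ii)
        foreign = owner[ii] != i
        masked = np.where(foreign, dd, np.inf)
        best = masked.min()
        if not np.isfinite(best):
            # fall back to brute force against all foreign points
            others = all_pts[owner != i]
            diff = pts[:, None, :] - others[None, :, :]
            best = np.sqrt((diff**2).sum(-1)).min()
        dists.append(best * cell_size)
    return float(np.mean(dists))


def class_metrics(
    patches: PatchSet,
    extent: np.ndarray,
    cell_size: float,
) -> dict:
    """MPS (ha), ED (m/ha), ENN_MN (m) and patch count over an extent.

    MPS = class area / n_patches; ED = class edge length inside the extent
    per hectare of extent; ENN_MN = mean over patches of the nearest
    other-patch edge-to-edge (cell-center) distance.  With no patches the
    metrics are undefined (NaN, ``defined=False``).
    """
    extent = np.asarray(extent, dtype=bool)
    cm = patches.labels > 0
    n = patches.n_patches
    cell_ha = (cell_size**2) / 10_000.0
    extent_ha = float(extent.sum()) * cell_ha
    if n == 0:
        return {
            "n_patches": 0,
            "mps_ha": float("nan"),
            "ed_m_per_ha": float("nan"),
            "enn_mn_m": float("nan"),
            "defined": False,
        }
    area_ha = float(cm.sum()) * cell_ha
    ed = _edge_length_m(cm, extent, cell_size) / extent_ha if extent_ha > 0 else float("nan")
    return {
        "n_patches": n,
        "mps_ha": area_ha / n,
        "ed_m_per_ha": ed,
        "enn_mn_m": _enn_mean_m(patches, extent, cell_size),
        "defined": True,
    }


def urban_buffer(urban: np.ndarray, radius_m: float, cell_size: float) -> np.ndarray:
    """Cells whose center lies within ``radius_m`` of the nearest urban
    cell center, urban cells themselves excluded."""
    if radius_m <= 0:
        raise ValueError("radius must be > 0")
    urban = np.asarray(urban, dtype=bool)
    if not urban.any():
        return np.zeros_like(urban)
    dist = ndimage.distance_transform_edt(~urban, sampling=cell_size)
    return (dist > 0) & (dist <= radius_m + 1e-9)


def fragmentation_in_buffer(
    habitat_mask: np.ndarray,
    stack: ScenarioStack,
    zones: ZoneMap,
    radius_m: float = 5000.0,
    connectivity: int = 8,
    buffer_epoch: int | None = None,
) -> pd.DataFrame:
    """Patch metrics of remaining habitat inside the urban buffer, per zone.

    The buffer region is drawn around urban land at ``buffer_epoch``
    (default: the final epoch) and held fixed; the region includes the
    reference urban footprint, so urban cells are part of the analysis
    extent and habitat-urban boundaries count as edge.  Habitat at epoch t
    is the baseline natural mask minus urban land at t.  Zones whose
    extent is empty are flagged ``defined=False`` and excluded from
    medians.
    """
    spec = stack.spec
    if zones.grid.spec != spec:
        raise ValueError("zone raster misaligned with stack")
    ref_epoch = stack.epochs[-1] if buffer_epoch is None else buffer_epoch
    ref_urban = stack.mask_at(ref_epoch)
    region = urban_buffer(ref_urban, radius_m, spec.cell_size) | ref_urban
    rows = []
    for epoch, urban in zip(stack.epochs, stack.masks):
        habitat_t = habitat_mask & ~urban
        for z in zones.zone_ids():
            extent = region & (zones.grid.codes == z)
            if not extent.any():
                rows.append(
                    {
                        "scenario": stack.scenario_id,
                        "epoch": epoch,
                        "zone_id": int(z),
                        "n_patches": 0,
                        "mps_ha": np.nan,
                        "ed_m_per_ha": np.nan,
                        "enn_mn_m": np.nan,
                        "defined": False,
                    }
                )
                continue
            patches = label_patches(habitat_t & extent, connectivity)
            m = class_metrics(patches, extent, spec.cell_size)
            rows.append(
                {
                    "scenario": stack.scenario_id,
                    "epoch": epoch,
                    "zone_id": int(z),
                    **m,
                }
            )
    return pd.DataFrame(rows)


def median_metrics_across_zones(frag: pd.DataFrame) -> pd.DataFrame:
    """Median MPS/ED/ENN_MN across zones per scenario/epoch (defined rows)."""
    ok = frag[frag["defined"]]
    return (
        ok.groupby(["scenario", "epoch"])[["mps_ha", "ed_m_per_ha", "enn_mn_m"]]
        .median()
        .reset_index()
    )


def _mean_edge_distance_m(
    urban: np.ndarray,
    habitat_class_mask: np.ndarray,
    extent: np.ndarray,
    cell_size: float,
) -> float:
    """Mean over urban edge cells of the distance to the nearest
    habitat-class edge cell (cell centers)."""
    u_edge = edge_cells(urban, extent)
    h_edge = edge_cells(habitat_class_mask, extent)
    if not u_edge.any() or not h_edge.any():
        return float("nan")
    dist = ndimage.distance_transform_edt(~h_edge, sampling=cell_size)
    return float(dist[u_edge].mean())


def edge_distance_series(
    stack: ScenarioStack,
    habitat: CategoricalGrid,
    natural_mask: np.ndarray,
    zones: ZoneMap | None = None,
) -> pd.DataFrame:
    """Urban-edge to habitat-edge distances per epoch and their change.

    For every epoch and habitat class (plus the pooled "natural" class),
    the mean distance from urban patch edge cells to the nearest patch
    edge cells of that class is computed; habitat at epoch t excludes
    cells already urbanized.  ``effect_change = d_prev - d_curr``: positive
    means urban land moved closer to habitat.  With ``zones`` the record
    is computed per zone, else for the whole grid (zone_id "ALL").
    """
    spec = stack.spec
    extent_all = ~habitat.mask
    units: list[tuple[str, np.ndarray]] = [("ALL", np.ones(spec.shape, dtype=bool))]
    if zones is not None:
        if zones.grid.spec != spec:
            raise ValueError("zone raster misaligned with stack")
        units = [(str(z), zones.grid.codes == z) for z in zones.zone_ids()]

    class_masks: dict[str, np.ndarray] = {"natural": natural_mask}
    for code, name in habitat.legend.items():
        if name in ("cropland", "urban"):
            continue
        cm = habitat.codes == code
        if cm.any():
            class_masks[name] = cm

    rows = []
    for zone_id, zsel in units:
        extent = extent_all & zsel
        for cls, cm in class_masks.items():
            prev = None
            for epoch, urban in zip(stack.epochs, stack.masks):
                d = _mean_edge_distance_m(
                    urban & zsel, cm & ~urban & zsel, extent, spec.cell_size
                )
                rows.append(
                    {
                        "scenario": stack.scenario_id,
                        "zone_id": zone_id,
                        "habitat_class": cls,
                        "epoch": epoch,
                        "mean_distance_m": d,
                        "effect_change_m": (prev - d)
                        if prev is not None and np.isfinite(prev) and np.isfinite(d)
                        else np.nan,
                        "defined": bool(np.isfinite(d)),
                    }
                )
                prev = d
    return pd.DataFrame(rows)
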