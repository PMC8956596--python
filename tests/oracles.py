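"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (double loops, flood fill, all-pairs
distances) and share no code with the package internals.
"""

from __future__ import annotations

import numpy as np

FOUR = ((-1, 0), (1, 0), (0, -1), (0, 1))
EIGHT = FOUR + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels (1..n) by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    R, C = mask.shape
    nbrs = FOUR if connectivity == 4 else EIGHT
    labels = np.zeros((R, C), dtype=int)
    nxt = 0
    for r0 in range(R):
        for c0 in range(C):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < R and 0 <= cc < C and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels


def brute_edge_cells(class_mask: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """Class cells with >= 1 different-class 4-neighbor inside the extent."""
    cm = np.asarray(class_mask, dtype=bool) & extent
    R, C = cm.shape
    out = np.zeros_like(cm)
    for r in range(R):
        for c in range(C):
            if not cm[r, c]:
                continue
            for dr, dc in FOUR:
                rr, cc = r + dr, c + dc
                if 0 <= rr < R and 0 <= cc < C and extent[rr, cc] and not cm[rr, cc]:
                    out[r, c] = True
                    break
    return out


def brute_edge_length(class_mask: np.ndarray, extent: np.ndarray, cell_size: float) -> float:
    """Total length of class/other shared sides inside the extent."""
    cm = np.asarray(class_mask, dtype=bool) & extent
    R, C = cm.shape
    sides = 0
    for r in range(R):
        for c in range(C):
            if not cm[r, c]:
                continue
            for dr, dc in FOUR:
                rr, cc = r + dr, c + dc
                if 0 <= rr < R and 0 <= cc < C and extent[rr, cc] and not cm[rr, cc]:
                    sides += 1
    return sides * cell_size


def brute_enn_mean(labels: np.ndarray, extent: np.ndarray, cell_size: float) -> float:
    """Mean over patches of the nearest other-patch edge-to-edge distance."""
    n = labels.max()
    if n < 2:
        return float("nan")
    cm = labels > 0
    edges = brute_edge_cells(cm, extent)
    pts = {}
    for pid in range(1, n + 1):
        sel = edges & (labels == pid)
        if not sel.any():
            sel = labels == pid
        pts[pid] = np.argwhere(sel)
    dists = []
    for pid in range(1, n + 1):
        best = np.inf
        for qid in range(1, n + 1):
            if qid == pid:
                continue
            diff = pts[pid][:, None, :] - pts[qid][None, :, :]
            d = np.sqrt((diff.astype(float) ** 2).sum(-1)).min()
            best = min(best, d)
        dists.append(best * cell_size)
    return float(np.mean(dists))


def brute_gi_star(values: np.ndarray, valid: np.ndarray, band_cells: float) -> np.ndarray:
    """Double-loop Gi* z-scores with binary band weights including self."""
    R, C = values.shape
    coords = np.argwhere(valid)
    xs = values[valid]
    n = len(xs)
    xbar = xs.mean()
    s = np.sqrt((xs**2).mean() - xbar**2)
    z = np.full((R, C), np.nan)
    for r, c in coords:
        wx = 0.0
        wi = 0
        for rr, cc in coords:
            if (r - rr) ** 2 + (c - cc) ** 2 <= band_cells**2 + 1e-12:
                wx += values[rr, cc]
                wi += 1
        if s == 0:
            z[r, c] = 0.0
            continue
        denom = s * np.sqrt((n * wi - wi**2) / (n - 1))
        z[r, c] = (wx - xbar * wi) / denom if denom > 0 else 0.0
    return z


def brute_mean_edge_distance(
    urban: np.ndarray, habitat: np.ndarray, extent: np.ndarray, cell_size: float
) -> float:
    """Mean over urban edge cells of distance to nearest habitat edge cell."""
    u_edge = np.argwhere(brute_edge_cells(urban, extent))
    h_edge = np.argwhere(brute_edge_cells(habitat, extent))
    if len(u_edge) == 0 or len(h_edge) == 0:
        return float("nan")
    dists = []
    for p in u_edge:
        dists.append(min(np.hypot(*(p - q)) for q in h_edge))
    return float(np.mean(dists)) * cell_size
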