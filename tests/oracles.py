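"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and the library
routines behind them) so that each check compares two independently written
computations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def exhaustive_otsu(values: np.ndarray, bins: int = 256) -> float:
    """Exhaustive search over all bin edges for the threshold minimizing
    weighted intra-class variance (histogram with bin centers as values)."""
    values = np.asarray(values, dtype=float)
    if values.min() == values.max():
        return float(values.min())
    hist, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    best_k, best_obj = 0, np.inf
    for k in range(bins):
        lo_w = hist[:k].sum()
        hi_w = hist[k:].sum()
        obj = 0.0
        if lo_w > 0:
            mu = (hist[:k] * centers[:k]).sum() / lo_w
            obj += lo_w / total * ((hist[:k] * (centers[:k] - mu) ** 2).sum() / lo_w)
        if hi_w > 0:
            mu = (hist[k:] * centers[k:]).sum() / hi_w
            obj += hi_w / total * ((hist[k:] * (centers[k:] - mu) ** 2).sum() / hi_w)
        if obj < best_obj - 1e-15:
            best_obj = obj
            best_k = k
    return float(edges[best_k])


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Breadth-first flood-fill connected-component labeling, raster order."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((H, W), dtype=np.int32)
    next_label = 0
    for r in range(H):
        for c in range(W):
            if mask[r, c] and labels[r, c] == 0:
                next_label += 1
                queue = deque([(r, c)])
                labels[r, c] = next_label
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < H and 0 <= nc < W and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = next_label
                            queue.append((nr, nc))
    return labels


def point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Scalar even-odd ray-casting test (half-open edge semantics)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if (y0 <= y) != (y1 <= y):
            xint = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            if x < xint:
                inside = not inside
    return inside
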