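"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: scalar loops
and explicit set arithmetic instead of vectorized numpy or library
morphology/labeling.
"""

from __future__ import annotations

import numpy as np


def point_in_polygon_evenodd(x: float, y: float, verts: np.ndarray) -> bool:
    """Scalar even-odd crossing test for one point."""
    inside = False
    n = len(verts)
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if ay == by:
            continue
        if (ay > y) != (by > y):
            x_cross = ax + (y - ay) * (bx - ax) / (by - ay)
            if x < x_cross:
                inside = not inside
    return inside


def rasterize_polygon_bruteforce(verts, dims) -> np.ndarray:
    h, w = dims
    out = np.zeros((h, w), dtype=bool)
    v = np.asarray(verts, dtype=float)
    for r in range(h):
        for c in range(w):
            out[r, c] = point_in_polygon_evenodd(c + 0.5, r + 0.5, v)
    return out


def erode_bruteforce(mask: np.ndarray, k: int) -> np.ndarray:
    """Binary erosion with a k×k square; outside the image is background."""
    h, w = mask.shape
    r = k // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < h and 0 <= jj < w) or not mask[ii, jj]:
                        ok = False
                        break
                if not ok:
                    break
            out[i, j] = ok
    return out


def dilate_bruteforce(mask: np.ndarray, k: int) -> np.ndarray:
    h, w = mask.shape
    r = k // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            hit = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                        hit = True
                        break
                if hit:
                    break
            out[i, j] = hit
    return out


def weak_label_bruteforce(patch: np.ndarray, params) -> np.ndarray:
    """Per-pixel threshold rule + open/close, all by scalar loops."""
    h, w = patch.shape[:2]
    lum = np.empty((h, w))
    raw = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (float(patch[i, j, c]) for c in range(3))
            lum[i, j] = (r + g + b) / 3.0
    cut = min(
        float(np.percentile(lum, params.luminance_percentile)), params.max_luminance
    )
    for i in range(h):
        for j in range(w):
            r, g = float(patch[i, j, 0]), float(patch[i, j, 1])
            ratio = r / max(g, 1.0)
            raw[i, j] = lum[i, j] <= cut and ratio < params.min_channel_ratio
    opened = dilate_bruteforce(erode_bruteforce(raw, params.open_kernel), params.open_kernel)
    closed = erode_bruteforce(dilate_bruteforce(opened, params.close_kernel), params.close_kernel)
    return closed


def flood_fill_components(mask: np.ndarray, connectivity: int = 2):
    """BFS flood-fill labeling; returns a list of frozensets of (r, c)."""
    h, w = mask.shape
    if connectivity == 2:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                comps.append(frozenset(comp))
    return comps
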