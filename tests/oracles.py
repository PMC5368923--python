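"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths they check: flood fill by
explicit BFS, Mann-Whitney by full enumeration of arrangements, rotation by
a directly-constructed affine resampler.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np

NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_components(img: np.ndarray) -> list[dict]:
    """8-connected components of a binary raster by explicit BFS.

    Returns a list of dicts with pixel count and bounding boxes, sorted by
    (row_min, col_min).
    """
    img = np.asarray(img, dtype=bool)
    seen = np.zeros_like(img)
    comps = []
    h, w = img.shape
    for sy in range(h):
        for sx in range(w):
            if not img[sy, sx] or seen[sy, sx]:
                continue
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            pixels = []
            while q:
                y, x = q.popleft()
                pixels.append((y, x))
                for dy, dx in NEIGHBORS8:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and img[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        q.append((ny, nx))
            ys = [p[0] for p in pixels]
            xs = [p[1] for p in pixels]
            comps.append(
                {
                    "size": len(pixels),
                    "row_min": min(ys),
                    "row_max": max(ys),
                    "col_min": min(xs),
                    "col_max": max(xs),
                }
            )
    comps.sort(key=lambda c: (c["row_min"], c["col_min"]))
    return comps


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label arrangements.

    Assumes no ties.  The p-value is the fraction of arrangements whose U
    statistic is at least as extreme (in either direction) as observed.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    n_a = len(a)

    def u_of(indices_a: tuple[int, ...]) -> float:
        xa = [pooled[i] for i in indices_a]
        xb = [pooled[i] for i in range(len(pooled)) if i not in indices_a]
        return sum(1.0 for x in xa for y in xb if x > y)

    observed = u_of(tuple(range(n_a)))
    mean_u = n_a * (len(b)) / 2.0
    dev = abs(observed - mean_u)
    total = extreme = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def kruskal_h_by_hand(groups) -> float:
    """Kruskal-Wallis H from the rank-sum formula (no tie correction;
    intended for tie-free inputs)."""
    pooled = sorted(v for g in groups for v in g)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    h = 0.0
    for g in groups:
        r = sum(ranks[v] for v in g)
        h += r * r / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def rotate_point_oracle(p, shape, angle_rad):
    """Forward-map an (x, y) point for a rotation by -angle about the image
    centre with the canvas expanded to hold all four corners."""
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    r = np.array([[ca, sa], [-sa, ca]])
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    q = (corners - c) @ r.T
    mn = q.min(axis=0)
    return r @ (np.asarray(p, float) - c) - mn
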