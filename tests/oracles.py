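"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — O(n²w²) window scans, BFS flood
fill, exhaustive permutation enumeration — and shares no code with the
package's optimized paths.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def sliding_window_bradley(
    plane: np.ndarray, halfwidth: int, sensitivity: float, mask: np.ndarray | None = None
) -> np.ndarray:
    """Naive per-pixel window-mean threshold (truncated borders)."""
    plane = np.asarray(plane, dtype=float)
    ny, nx = plane.shape
    out = np.zeros((ny, nx), dtype=bool)
    for y in range(ny):
        for x in range(nx):
            if mask is not None and not mask[y, x]:
                continue
            y0, y1 = max(y - halfwidth, 0), min(y + halfwidth + 1, ny)
            x0, x1 = max(x - halfwidth, 0), min(x + halfwidth + 1, nx)
            win = plane[y0:y1, x0:x1]
            if mask is not None:
                m = mask[y0:y1, x0:x1]
                if not m.any():
                    continue
                local_mean = win[m].mean()
            else:
                local_mean = win.mean()
            out[y, x] = plane[y, x] > local_mean * (1.0 + sensitivity)
    return out


_OFFSETS_6 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if abs(dz) + abs(dy) + abs(dx) == 1
]
_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def flood_fill_label(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling of a 3D binary volume."""
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=np.int32)
    nz, ny, nx = binary.shape
    current = 0
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not binary[z0, y0, x0] or labels[z0, y0, x0]:
                    continue
                current += 1
                queue = deque([(z0, y0, x0)])
                labels[z0, y0, x0] = current
                while queue:
                    z, y, x = queue.popleft()
                    for dz, dy, dx in offsets:
                        z1, y1, x1 = z + dz, y + dy, x + dx
                        if (
                            0 <= z1 < nz
                            and 0 <= y1 < ny
                            and 0 <= x1 < nx
                            and binary[z1, y1, x1]
                            and not labels[z1, y1, x1]
                        ):
                            labels[z1, y1, x1] = current
                            queue.append((z1, y1, x1))
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two labelings induce the same partition of the foreground."""
    a, b = np.asarray(a), np.asarray(b)
    if (a > 0).sum() != (b > 0).sum() or ((a > 0) != (b > 0)).any():
        return False
    pairs = set(zip(a[a > 0].ravel(), b[a > 0].ravel()))
    # bijection between label sets
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a (number of (a_i, b_j) pairs with a_i > b_j,
    ties counting half)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def exact_mann_whitney_p(a, b) -> float:
    """Two-sided exact Mann–Whitney p-value by exhaustive enumeration.

    Enumerates every C(n_a + n_b, n_a) assignment of the pooled sample and
    counts assignments at least as extreme (two-sided: doubled smaller tail,
    capped at 1) as the observed U.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = a.size
    u_obs = mann_whitney_u(a, b)
    us = []
    idx_all = frozenset(range(pooled.size))
    for picks in combinations(range(pooled.size), n_a):
        rest = sorted(idx_all - set(picks))
        us.append(mann_whitney_u(pooled[list(picks)], pooled[rest]))
    us = np.array(us)
    eps = 1e-12
    p_low = np.mean(us <= u_obs + eps)
    p_high = np.mean(us >= u_obs - eps)
    return float(min(2.0 * min(p_low, p_high), 1.0))


def percentile_subtract_clip(plane: np.ndarray, fraction: float) -> np.ndarray:
    """Sort-based percentile baseline subtraction with clipping at zero."""
    flat = np.sort(plane.ravel())
    baseline = np.quantile(flat, fraction)
    return np.clip(plane - baseline, 0.0, None)
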