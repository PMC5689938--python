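"""Brute-force reference implementations of the texture matrices.

Deliberately naive (explicit Python loops, BFS flood fill) and independent
of the vectorized builders in ``petrad.texture_features``.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def glcm_bruteforce(levels, mask, ng, directions):
    """Double loop over all voxels and offsets; symmetric, normalized."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    counts = np.zeros((ng, ng), dtype=np.int64)
    shape = mask.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in directions:
                    for sgn in (1, -1):
                        nx, ny, nz = x + sgn * dx, y + sgn * dy, z + sgn * dz
                        if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                            continue
                        if not mask[nx, ny, nz]:
                            continue
                        counts[levels[x, y, z] - 1, levels[nx, ny, nz] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def glrlm_bruteforce(levels, mask, ng, directions):
    """Scan every maximal run per direction by explicit walking."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape

    def inside(p):
        return all(0 <= p[i] < shape[i] for i in range(3)) and mask[p]

    runs = {}
    for d in directions:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    p = (x, y, z)
                    if not mask[p]:
                        continue
                    lv = levels[p]
                    prev = (x - d[0], y - d[1], z - d[2])
                    if inside(prev) and levels[prev] == lv:
                        continue
                    length = 1
                    q = (x + d[0], y + d[1], z + d[2])
                    while inside(q) and levels[q] == lv:
                        length += 1
                        q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                    runs[(lv, length)] = runs.get((lv, length), 0) + 1
    rmax = max(l for _, l in runs)
    mat = np.zeros((ng, rmax), dtype=np.int64)
    for (lv, length), c in runs.items():
        mat[lv - 1, length - 1] = c
    return mat


def glszm_bruteforce(levels, mask, ng):
    """BFS flood fill of equal-level zones under 26-connectivity."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    zones = {}
    nbrs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lv = levels[x, y, z]
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx, dy, dz in nbrs:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                            continue
                        if seen[nx, ny, nz] or not mask[nx, ny, nz]:
                            continue
                        if levels[nx, ny, nz] != lv:
                            continue
                        seen[nx, ny, nz] = True
                        queue.append((nx, ny, nz))
                zones[(lv, size)] = zones.get((lv, size), 0) + 1
    smax = max(s for _, s in zones)
    mat = np.zeros((ng, smax), dtype=np.int64)
    for (lv, s), c in zones.items():
        mat[lv - 1, s - 1] = c
    return mat


def ngtdm_bruteforce(levels, mask, ng, halfwidth=3):
    """Per-voxel loop over the (2h+1)x(2h+1) in-plane window, in-mask only."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng)
    scored = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                vals = []
                for dx in range(-halfwidth, halfwidth + 1):
                    for dy in range(-halfwidth, halfwidth + 1):
                        if dx == 0 and dy == 0:
                            continue
                        nx, ny = x + dx, y + dy
                        if not (0 <= nx < shape[0] and 0 <= ny < shape[1]):
                            continue
                        if mask[nx, ny, z]:
                            vals.append(levels[nx, ny, z])
                if not vals:
                    continue
                lv = levels[x, y, z]
                n[lv - 1] += 1
                s[lv - 1] += abs(lv - float(np.mean(vals)))
                scored += 1
    return n, s, scored
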