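"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (pure-Python loops, explicit
definitions) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBOURS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
NEIGHBOURS_8 = NEIGHBOURS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_components(slice_mask: np.ndarray, connectivity: int) -> list[int]:
    """Connected-component areas of a 2D boolean mask by BFS flood fill."""
    nbrs = NEIGHBOURS_4 if connectivity == 4 else NEIGHBOURS_8
    seen = np.zeros_like(slice_mask, dtype=bool)
    ny, nx = slice_mask.shape
    areas = []
    for sy in range(ny):
        for sx in range(nx):
            if not slice_mask[sy, sx] or seen[sy, sx]:
                continue
            queue = [(sy, sx)]
            seen[sy, sx] = True
            area = 0
            while queue:
                y, x = queue.pop()
                area += 1
                for dy, dx in nbrs:
                    yy, xx = y + dy, x + dx
                    if (
                        0 <= yy < ny and 0 <= xx < nx
                        and slice_mask[yy, xx] and not seen[yy, xx]
                    ):
                        seen[yy, xx] = True
                        queue.append((yy, xx))
            areas.append(area)
    return sorted(areas)


def rasterise_tube_slice(
    shape: tuple[int, int],
    p0: tuple[float, float, float],
    p1: tuple[float, float, float],
    radius_vox: float,
    z: int,
) -> np.ndarray:
    """Paint one slice of a straight tube by per-pixel distance test.

    A pixel (y, x) in slice z belongs to the tube when its centre's 3D
    distance to the segment p0-p1 (in (z, y, x) voxel coordinates) is at
    most the radius. For a slice-axis-parallel tube this is the
    centre-in-disk rule.
    """
    ny, nx = shape
    out = np.zeros(shape, dtype=bool)
    dz, dy, dx = (p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2])
    len2 = dz * dz + dy * dy + dx * dx
    for y in range(ny):
        for x in range(nx):
            rz, ry, rx = z - p0[0], y - p0[1], x - p0[2]
            if len2 == 0:
                t = 0.0
            else:
                t = max(0.0, min(1.0, (rz * dz + ry * dy + rx * dx) / len2))
            ez, ey, ex = rz - t * dz, ry - t * dy, rx - t * dx
            if ez * ez + ey * ey + ex * ex <= radius_vox * radius_vox:
                out[y, x] = True
    return out


def decade_bin_counts(areas, uppers) -> list[int]:
    """Assign each area to the first bin whose upper bound covers it."""
    counts = [0] * len(uppers)
    for a in areas:
        for i, u in enumerate(uppers):
            if a <= u:
                counts[i] += 1
                break
    return counts


def midranks(values) -> list[float]:
    """Mid-ranks (average rank for ties), 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def rank_pearson(x, y) -> float:
    """Spearman's rho via explicit rank transform then Pearson formula."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def anova_f(groups) -> tuple[float, int, int]:
    """One-way ANOVA F by explicit sums-of-squares arithmetic."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    df1, df2 = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2


def pooled_two_sample_t(a, b) -> float:
    """Two-sample t with pooled variance."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def brute_closing(mask2d: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing (dilate then erode) with a square structuring element."""
    ny, nx = mask2d.shape

    def dilate(m):
        out = np.zeros_like(m)
        for y in range(ny):
            for x in range(nx):
                y0, y1 = max(0, y - radius), min(ny, y + radius + 1)
                x0, x1 = max(0, x - radius), min(nx, x + radius + 1)
                if m[y0:y1, x0:x1].any():
                    out[y, x] = True
        return out

    def erode(m):
        out = np.zeros_like(m)
        for y in range(ny):
            for x in range(nx):
                y0, y1 = max(0, y - radius), min(ny, y + radius + 1)
                x0, x1 = max(0, x - radius), min(nx, x + radius + 1)
                if m[y0:y1, x0:x1].all():
                    out[y, x] = True
        return out

    return erode(dilate(mask2d))
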