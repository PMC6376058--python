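"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain enumeration (nested loops, flood
fill, explicit ANOVA sums of squares) so it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np

OFFSETS_4 = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def glcm_enumeration(levels, mask, offsets=OFFSETS_4):
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    ng = int(levels[mask].max())
    m = np.zeros((ng, ng))
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    m[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                    m[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    return m


def glrlm_enumeration(levels, mask, offsets=OFFSETS_4):
    """Run-length counts: walk every maximal run in every direction."""
    h, w = levels.shape
    ng = int(levels[mask].max())
    runs = []
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                # run start: predecessor along (dr,dc) absent or different
                pr, pc = r - dr, c - dc
                if (
                    0 <= pr < h
                    and 0 <= pc < w
                    and mask[pr, pc]
                    and levels[pr, pc] == levels[r, c]
                ):
                    continue
                length = 1
                rr, cc = r + dr, c + dc
                while (
                    0 <= rr < h
                    and 0 <= cc < w
                    and mask[rr, cc]
                    and levels[rr, cc] == levels[r, c]
                ):
                    length += 1
                    rr += dr
                    cc += dc
                runs.append((int(levels[r, c]), length))
    max_len = max(length for _, length in runs)
    m = np.zeros((ng, max_len))
    for level, length in runs:
        m[level - 1, length - 1] += 1
    return m


def glszm_enumeration(levels, mask):
    """Zone sizes by explicit 8-connected flood fill per level."""
    h, w = levels.shape
    ng = int(levels[mask].max())
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGHBORS_8:
                    nr, nc = cr + dr, cc + dc
                    if (
                        0 <= nr < h
                        and 0 <= nc < w
                        and mask[nr, nc]
                        and not seen[nr, nc]
                        and levels[nr, nc] == level
                    ):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            zones.append((int(level), size))
    max_size = max(s for _, s in zones)
    m = np.zeros((ng, max_size))
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return m


def ngtdm_enumeration(levels, mask):
    """(n_i, s_i) by explicit neighbourhood enumeration."""
    h, w = levels.shape
    ng = int(levels[mask].max())
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neighbors = []
            for dr, dc in NEIGHBORS_8:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                    neighbors.append(levels[nr, nc])
            if not neighbors:
                continue
            i = int(levels[r, c])
            n_i[i - 1] += 1
            s_i[i - 1] += abs(i - float(np.mean(neighbors)))
    return n_i, s_i


def icc_anova_oracle(x, y):
    """ICC(A,k) via explicit two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = 2
    data = np.column_stack([x, y])
    grand = data.sum() / (n * k)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)


def ccc_oracle(x, y):
    """Lin's concordance by direct formula with population moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * sxy / (vx + vy + (mx - my) ** 2)


def geodesic_bfs_oracle(mask, spacing):
    """All-pairs within-mask shortest paths by Dijkstra on explicit lists."""
    import heapq

    coords = [tuple(p) for p in np.argwhere(mask)]
    index = {p: i for i, p in enumerate(coords)}
    # boundary pixels: any 8-neighbor outside the mask or the image
    h, w = mask.shape
    boundary = []
    for r, c in coords:
        for dr, dc in NEIGHBORS_8:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w) or not mask[nr, nc]:
                boundary.append((r, c))
                break
    best = 0.0
    for src in boundary:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, (r, c) = heapq.heappop(heap)
            if d > dist.get((r, c), np.inf):
                continue
            for dr, dc in NEIGHBORS_8:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                    step = np.hypot(dr * spacing[0], dc * spacing[1])
                    nd = d + step
                    if nd < dist.get((nr, nc), np.inf):
                        dist[(nr, nc)] = nd
                        heapq.heappush(heap, (nd, (nr, nc)))
        best = max(best, max(dist[b] for b in boundary if b in dist))
    return best
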