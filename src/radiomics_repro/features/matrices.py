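"""Grey-level texture matrices: GLCM, GLRLM, GLSZM, NGTDM.

All matrices are built on the discretized level grid, restricted to ROI
pixels: pairs, runs and neighbourhoods never cross the ROI boundary.
Directional matrices (GLCM, GLRLM) use the four standard 2D angles
(0, 45, 90, 135 degrees) at distance 1 and are *summed* over directions
into a single merged matrix before normalisation.  Grey levels are the
actual occupied integer levels 1..n_levels; rows for unoccupied levels are
kept (they carry zero counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedROI

#: (row, col) offsets for the four 2D angles at distance 1.
ANGLES_2D: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class TextureMatrix:
    """A grey-level texture matrix plus its construction metadata.

    ``matrix`` holds non-negative counts for GLCM (levels x levels),
    GLRLM (levels x run lengths) and GLSZM (levels x zone sizes).  For
    NGTDM it is the (levels, 2) stack of column vectors ``n_i`` (pixel
    counts) and ``s_i`` (summed absolute grey-tone differences).
    """

    kind: str
    matrix: np.ndarray
    n_levels: int
    n_roi_pixels: int
    directions: tuple[tuple[int, int], ...] | None = None

    @property
    def normalized(self) -> np.ndarray:
        """Counts normalised to a probability distribution (sums to 1)."""
        total = self.matrix.sum()
        if total == 0:
            return np.zeros_like(self.matrix, dtype=float)
        return self.matrix / total


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]):
    """Level pairs (a, b) for all in-ROI pixel pairs at the given offset."""
    dr, dc = offset
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src_mask = mask[r0:r1, c0:c1]
    dst_mask = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = src_mask & dst_mask
    a = levels[r0:r1, c0:c1][valid]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
    return a, b


def build_glcm(
    discretized: DiscretizedROI,
    distance: int = 1,
    angles: tuple[tuple[int, int], ...] = ANGLES_2D,
) -> TextureMatrix:
    """Symmetric grey-level co-occurrence matrix merged over angles.

    Only pixel pairs with both pixels inside the ROI are counted; each
    pair contributes to (i, j) and (j, i), so the matrix is symmetric by
    construction.
    """
    ng = discretized.n_levels
    levels = discretized.levels
    mask = discretized.mask
    counts = np.zeros((ng, ng), dtype=float)
    for dr, dc in angles:
        a, b = _shifted_pairs(levels, mask, (dr * distance, dc * distance))
        np.add.at(counts, (a - 1, b - 1), 1.0)
        np.add.at(counts, (b - 1, a - 1), 1.0)
    return TextureMatrix(
        kind="GLCM",
        matrix=counts,
        n_levels=ng,
        n_roi_pixels=int(mask.sum()),
        directions=angles,
    )


def _line_runs(line: np.ndarray):
    """Yield (level, run_length) for maximal runs of equal nonzero level."""
    start = 0
    n = line.size
    for i in range(1, n + 1):
        if i == n or line[i] != line[start]:
            if line[start] != 0:
                yield int(line[start]), i - start
            start = i


def _directional_lines(levels: np.ndarray, offset: tuple[int, int]):
    """The scan lines of the grid along one of the four angles."""
    dr, dc = offset
    if (dr, dc) == (0, 1):
        yield from levels
    elif (dr, dc) == (-1, 0):
        yield from levels.T
    elif (dr, dc) == (-1, 1):  # anti-diagonals, scanned upward-right
        flipped = levels[::-1]
        for k in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, k)
    elif (dr, dc) == (-1, -1):  # main diagonals
        flipped = levels[::-1, ::-1]
        for k in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, k)
    else:
        raise ValueError(f"unsupported direction {offset}")


def build_glrlm(
    discretized: DiscretizedROI,
    angles: tuple[tuple[int, int], ...] = ANGLES_2D,
) -> TextureMatrix:
    """Grey-level run-length matrix merged (summed) over the four angles.

    Runs are maximal sequences of equal level along a direction, truncated
    at the ROI boundary (out-of-ROI pixels break runs).
    """
    ng = discretized.n_levels
    runs: list[tuple[int, int]] = []
    for offset in angles:
        for line in _directional_lines(discretized.levels, offset):
            runs.extend(_line_runs(np.asarray(line)))
    max_len = max((length for _, length in runs), default=1)
    counts = np.zeros((ng, max_len), dtype=float)
    for level, length in runs:
        counts[level - 1, length - 1] += 1.0
    return TextureMatrix(
        kind="GLRLM",
        matrix=counts,
        n_levels=ng,
        n_roi_pixels=int(discretized.mask.sum()),
        directions=angles,
    )


def build_glszm(discretized: DiscretizedROI, connectivity: int = 8) -> TextureMatrix:
    """Grey-level size-zone matrix (zones = connected equal-level regions)."""
    if connectivity == 8:
        structure = _STRUCT8
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    ng = discretized.n_levels
    levels = discretized.levels
    zones: list[tuple[int, int]] = []
    for lv in np.unique(levels[discretized.mask]):
        labelled, n_comp = ndimage.label(levels == lv, structure=structure)
        sizes = np.bincount(labelled.ravel())[1:]
        zones.extend((int(lv), int(s)) for s in sizes)
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((ng, max_size), dtype=float)
    for level, size in zones:
        counts[level - 1, size - 1] += 1.0
    return TextureMatrix(
        kind="GLSZM",
        matrix=counts,
        n_levels=ng,
        n_roi_pixels=int(discretized.mask.sum()),
    )


def build_ngtdm(discretized: DiscretizedROI) -> TextureMatrix:
    """Neighbourhood grey-tone difference vectors (n_i, s_i).

    For every ROI pixel with at least one ROI pixel in its 8-neighbourhood,
    the absolute difference between its level and the mean level of those
    neighbours is accumulated into ``s_i`` for its level ``i``; ``n_i``
    counts the contributing pixels.
    """
    ng = discretized.n_levels
    levels = discretized.levels.astype(float)
    mask = discretized.mask
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    neighbor_sum = ndimage.convolve(
        np.where(mask, levels, 0.0), kernel, mode="constant", cval=0.0
    )
    neighbor_cnt = ndimage.convolve(
        mask.astype(float), kernel, mode="constant", cval=0.0
    )
    valid = mask & (neighbor_cnt > 0)
    diffs = np.zeros(levels.shape)
    diffs[valid] = np.abs(
        levels[valid] - neighbor_sum[valid] / neighbor_cnt[valid]
    )
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = discretized.levels[valid] - 1
    np.add.at(n_i, lv, 1.0)
    np.add.at(s_i, lv, diffs[valid])
    return TextureMatrix(
        kind="NGTDM",
        matrix=np.column_stack([n_i, s_i]),
        n_levels=ng,
        n_roi_pixels=int(mask.sum()),
    )
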