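"""Thirteen 2D shape (morphology) features of a binary ROI.

Shape features depend only on the mask and the pixel spacing, never on the
grey values.  All lengths are in mm and areas in mm^2; anisotropic spacing
is handled by working in physical coordinates throughout.

Conventions
-----------
* Perimeters are lengths of the 0.5-level marching-squares contour of the
  mask (holes included), so the ROI perimeter and the convex-hull perimeter
  are measured identically and their ratio (Perimeter Solidity) is
  well-defined.
* Axis lengths derive from the second central moments of the pixel-center
  coordinates: the major (minor) axis is ``4 * sqrt(lambda)`` for the
  larger (smaller) covariance eigenvalue, matching the normalisation that
  recovers the side of a filled square and the axes of a filled ellipse.
* The maximum geodesic diameter is the longest within-mask shortest path
  between boundary pixels, on the 8-connected pixel graph with physical
  edge lengths.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist
from skimage.measure import find_contours
from skimage.morphology import convex_hull_image

SHAPE_FEATURE_NAMES: tuple[str, ...] = (
    "ConvexArea",
    "Deficit",
    "Eccentricity",
    "Elongation",
    "Extension",
    "MajorAxisLength",
    "MaximumDiameter",
    "MaximumGeodesicDiameter",
    "MinorAxisLength",
    "Perimeter",
    "PerimeterSolidity",
    "Solidity",
    "SurfaceArea",
)

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _contour_perimeter(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    """Total length (mm) of the 0.5-level contours of the padded mask."""
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        phys = contour * np.asarray(spacing)
        seg = np.diff(phys, axis=0)
        total += float(np.sqrt((seg**2).sum(axis=1)).sum())
    return total


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    return mask & ~eroded


def _geodesic_diameter(
    mask: np.ndarray, spacing: tuple[float, float], boundary: np.ndarray
) -> float:
    """Longest within-mask shortest path between boundary pixel centers."""
    coords = np.argwhere(mask)
    n = coords.shape[0]
    if n == 1:
        return 0.0
    index = -np.ones(mask.shape, dtype=np.int64)
    index[mask] = np.arange(n)
    rows, cols, weights = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        w = float(np.hypot(dr * spacing[0], dc * spacing[1]))
        src = coords
        dst = coords + (dr, dc)
        ok = (
            (dst[:, 0] >= 0)
            & (dst[:, 0] < mask.shape[0])
            & (dst[:, 1] >= 0)
            & (dst[:, 1] < mask.shape[1])
        )
        ok[ok] &= mask[dst[ok, 0], dst[ok, 1]]
        rows.append(index[src[ok, 0], src[ok, 1]])
        cols.append(index[dst[ok, 0], dst[ok, 1]])
        weights.append(np.full(int(ok.sum()), w))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    sources = index[boundary]
    dist = dijkstra(graph, directed=False, indices=sources)
    return float(dist[:, sources].max())


def compute_shape(mask: np.ndarray, spacing: tuple[float, float]) -> dict[str, float]:
    """Compute the 13 shape features of a single-component binary mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    spacing = (float(spacing[0]), float(spacing[1]))
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    if (
        mask[0, :].any()
        or mask[-1, :].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
    ):
        warnings.warn(
            "mask touches the image border; hull and perimeter are still computed",
            stacklevel=2,
        )

    pixel_area = spacing[0] * spacing[1]
    n_pix = int(mask.sum())
    area = n_pix * pixel_area

    hull = convex_hull_image(mask)
    convex_area = int(hull.sum()) * pixel_area
    solidity = area / convex_area
    deficit = 1.0 - solidity

    coords = np.argwhere(mask).astype(float) * np.asarray(spacing)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n_pix
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.clip(lam, 0.0, None)
    major = 4.0 * np.sqrt(lam[0])
    minor = 4.0 * np.sqrt(lam[1])
    if lam[0] > 0:
        eccentricity = float(np.sqrt(1.0 - lam[1] / lam[0]))
        elongation = float(minor / major)
    else:  # single pixel / degenerate
        eccentricity = np.nan
        elongation = np.nan

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox_area = (
        (rows[-1] - rows[0] + 1) * spacing[0] * (cols[-1] - cols[0] + 1) * spacing[1]
    )
    extension = area / bbox_area

    perimeter = _contour_perimeter(mask, spacing)
    hull_perimeter = _contour_perimeter(hull, spacing)
    perimeter_solidity = hull_perimeter / perimeter if perimeter > 0 else np.nan

    boundary = _boundary_pixels(mask)
    bcoords = np.argwhere(boundary).astype(float) * np.asarray(spacing)
    max_diam = float(pdist(bcoords).max()) if bcoords.shape[0] > 1 else 0.0
    max_geo = _geodesic_diameter(mask, spacing, boundary)

    return {
        "ConvexArea": convex_area,
        "Deficit": deficit,
        "Eccentricity": eccentricity,
        "Elongation": elongation,
        "Extension": extension,
        "MajorAxisLength": float(major),
        "MaximumDiameter": max_diam,
        "MaximumGeodesicDiameter": max_geo,
        "MinorAxisLength": float(minor),
        "Perimeter": perimeter,
        "PerimeterSolidity": perimeter_solidity,
        "Solidity": solidity,
        "SurfaceArea": area,
    }
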