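"""Fifteen first-order (intensity-statistics) features.

All statistics except Entropy and Uniformity are computed from the raw ROI
values; Entropy and Uniformity use the histogram of the discretized grey
levels, per the usual fixed-bin-size convention.  Moments use the
population (divisor N) form, and Kurtosis is the raw fourth standardized
moment (a Gaussian scores 3, no excess correction).  Skewness and Kurtosis
of a constant or single-pixel ROI are flagged missing (NaN).
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedROI

FIRSTORDER_FEATURE_NAMES: tuple[str, ...] = (
    "Energy",
    "Entropy",
    "Inter1090",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MAD",
    "Median",
    "Minimum",
    "Npix",
    "Range",
    "RMS",
    "Skewness",
    "STD",
    "Uniformity",
)


def compute_first_order(
    roi_values: np.ndarray, discretized: DiscretizedROI
) -> dict[str, float]:
    x = np.asarray(roi_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    std = float(x.std())  # population, divisor N
    if std > 0 and n > 1:
        z = (x - mean) / std
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4))
    else:
        skewness = np.nan
        kurtosis = np.nan

    levels = discretized.levels[discretized.mask]
    counts = np.bincount(levels)[1:]  # drop level 0 (outside ROI)
    p = counts[counts > 0] / levels.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    p10, p90 = np.percentile(x, [10, 90])
    return {
        "Energy": float((x**2).sum()),
        "Entropy": entropy,
        "Inter1090": float(p90 - p10),
        "Kurtosis": kurtosis,
        "Maximum": float(x.max()),
        "Mean": mean,
        "MAD": float(np.abs(x - mean).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Npix": float(n),
        "Range": float(x.max() - x.min()),
        "RMS": float(np.sqrt((x**2).mean())),
        "Skewness": skewness,
        "STD": std,
        "Uniformity": uniformity,
    }
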