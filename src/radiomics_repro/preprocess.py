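"""ADC-map computation and grey-level discretization.

Discretization is *absolute* (fixed bin size, IBSI "FBS"): intensities are
mapped to integer levels with a constant bin width anchored at 0, so
``level(x) = floor(x / w) + 1``.  Because ADC values expressed in
10^-3 mm^2/s would all collapse into a single bin of width 20, ADC maps are
rescaled by :data:`ADC_DISCRETIZATION_SCALE` (to 10^-6 mm^2/s, the common
scanner integer convention) before binning; the constant is carried in
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SequenceImage

#: Multiplier applied to ADC pixel values (stored in 10^-3 mm^2/s) before
#: absolute discretization, so that a bin width of 20 spans the
#: physiological range instead of collapsing it into one bin.
ADC_DISCRETIZATION_SCALE = 1000.0


@dataclass
class DiscretizedROI:
    """Integer grey levels over the ROI grid plus the raw values.

    ``levels`` has the shape of the input grid and holds
    ``floor(x / bin_width) + 1`` inside the ROI and 0 outside; ``mask``
    marks the ROI; ``n_levels`` is the maximum occupied level and sizes
    every texture matrix downstream; ``raw_values`` are the ROI pixel
    values in row-major order.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float
    raw_values: np.ndarray


def compute_adc(
    b_low_img: SequenceImage,
    b_high_img: SequenceImage,
    b_low: float = 0.0,
    b_high: float = 1000.0,
) -> SequenceImage:
    """Compute an ADC map from two diffusion weightings.

    The apparent diffusion coefficient is the per-pixel log-linear slope of
    signal decay, ``ADC = ln(S_low / S_high) / (b_high - b_low)`` in mm^2/s,
    returned in units of 10^-3 mm^2/s.  Pixels where either signal is
    non-positive are flagged as missing (NaN).  Negative ADC (signal
    increase) is preserved, not clipped.
    """
    if b_high <= b_low:
        raise ValueError(f"b_high ({b_high}) must exceed b_low ({b_low})")
    if b_low_img.pixels.shape != b_high_img.pixels.shape:
        raise ValueError(
            f"grid mismatch: b={b_low} image {b_low_img.pixels.shape} vs "
            f"b={b_high} image {b_high_img.pixels.shape}"
        )
    s0 = b_low_img.pixels
    s1 = b_high_img.pixels
    valid = (s0 > 0) & (s1 > 0)
    adc = np.full(s0.shape, np.nan)
    adc[valid] = np.log(s0[valid] / s1[valid]) / (b_high - b_low)
    # NaN pixels violate the SequenceImage finiteness invariant on purpose:
    # the map is assembled directly, keeping the missing-value flags.
    out = SequenceImage.__new__(SequenceImage)
    out.pixels = adc * 1e3  # mm^2/s -> 10^-3 mm^2/s
    out.spacing = b_low_img.spacing
    out.sequence_label = "ADC"
    out.patient_id = b_low_img.patient_id
    out.side = b_low_img.side
    return out


def discretize(
    values: np.ndarray,
    bin_width: float = 20.0,
    mask: np.ndarray | None = None,
) -> DiscretizedROI:
    """Absolute (fixed-bin-size) discretization anchored at 0.

    Values in [0, w) map to level 1, [w, 2w) to level 2, and so on.  When
    ``mask`` is given, only pixels inside it are binned; the returned
    ``levels`` grid is 0 outside.  Negative inputs are rejected: shift the
    signal to be non-negative before binning.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != values.shape:
            raise ValueError(
                f"grid mismatch: values {values.shape} vs mask {mask.shape}"
            )
    x = values[mask]
    if x.size == 0:
        raise ValueError("empty ROI")
    if np.any(x < 0):
        raise ValueError(
            "negative input values: absolute discretization is anchored at 0; "
            "shift the signal to be non-negative first"
        )
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[mask] = np.floor(x / bin_width).astype(np.int64) + 1
    return DiscretizedROI(
        levels=levels,
        mask=mask,
        n_levels=int(levels[mask].max()),
        bin_width=float(bin_width),
        raw_values=x,
    )
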