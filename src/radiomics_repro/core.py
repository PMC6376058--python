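"""Core domain containers shared across the pipeline.

The unit of analysis is one 2D grey-level slice of one MR sequence
(:class:`SequenceImage`) together with one or more observer delineations
(:class:`Delineation`).  Six sequence contrasts and three reading sessions
(L1 by reader 1; L2.1 and L2.2 by reader 2) form the full design of a case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: Closed set of sequence contrasts handled by the pipeline.
SEQUENCE_LABELS: tuple[str, ...] = (
    "T1",
    "ADC",
    "ipDIXON_T2",
    "wDIXON_T2",
    "PC_ipDIXON_T1",
    "PC_wDIXON_T1",
)

#: Reading sessions: L1 = reader 1; L2.1 / L2.2 = reader 2, two sessions.
READINGS: tuple[str, ...] = ("L1", "L2.1", "L2.2")

SIDES: tuple[str, ...] = ("left", "right")

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class SequenceImage:
    """One 2D grey-level slice of a single MR sequence.

    Parameters
    ----------
    pixels
        2D float array of signal values.  ADC maps are stored in units of
        10^-3 mm^2/s.
    spacing
        (row_mm, col_mm) pixel spacing, strictly positive.
    sequence_label
        One of :data:`SEQUENCE_LABELS`.
    patient_id, side
        Case identifiers; ``side`` is ``"left"`` or ``"right"``.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    sequence_label: str
    patient_id: str
    side: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.sequence_label not in SEQUENCE_LABELS:
            raise ValueError(
                f"unknown sequence label {self.sequence_label!r}; "
                f"expected one of {SEQUENCE_LABELS}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")


@dataclass
class Delineation:
    """One observer's binary ROI mask on the grid of its SequenceImage.

    The mask must contain at least one pixel and form exactly one
    8-connected component.
    """

    mask: np.ndarray
    reading: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.mask.shape}")
        if self.reading not in READINGS:
            raise ValueError(
                f"reading must be one of {READINGS}, got {self.reading!r}"
            )
        n = int(self.mask.sum())
        if n == 0:
            raise ValueError("mask is empty")
        _, n_comp = ndimage.label(self.mask, structure=_STRUCT8)
        if n_comp != 1:
            raise ValueError(
                f"mask has {n_comp} connected components (multiple components); "
                "exactly one 8-connected component is required"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def check_congruent(image: SequenceImage, delineation: Delineation) -> None:
    """Raise ``ValueError`` on any grid mismatch between image and mask."""
    if image.pixels.shape != delineation.mask.shape:
        raise ValueError(
            f"grid mismatch: image {image.pixels.shape} vs mask "
            f"{delineation.mask.shape}"
        )
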