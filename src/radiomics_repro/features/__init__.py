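"""Radiomics feature extraction: 85 named 2D features per ROI.

The schema is frozen: 13 shape, 15 first-order, 26 GLCM, 13 GLSZM,
13 GLRLM and 5 NGTDM features.  Duplicate short names across families
(Contrast, GLN, GLV, ...) are disambiguated by a family prefix in the
output schema, e.g. ``glcm_Contrast`` vs ``ngtdm_Contrast``.

Shape features consume only the mask and the pixel spacing; intensity and
texture features consume the grey values, with texture matrices built on
absolute fixed-bin-size discretized levels (pixel units, no spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import Delineation, SequenceImage, check_congruent
from ..preprocess import ADC_DISCRETIZATION_SCALE, discretize
from .firstorder import FIRSTORDER_FEATURE_NAMES, compute_first_order
from .matrices import (
    ANGLES_2D,
    TextureMatrix,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
)
from .shape import SHAPE_FEATURE_NAMES, compute_shape
from .texture import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

FAMILIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("shape", SHAPE_FEATURE_NAMES),
    ("firstorder", FIRSTORDER_FEATURE_NAMES),
    ("glcm", GLCM_FEATURE_NAMES),
    ("glszm", GLSZM_FEATURE_NAMES),
    ("glrlm", GLRLM_FEATURE_NAMES),
    ("ngtdm", NGTDM_FEATURE_NAMES),
)

#: The frozen, ordered 85-name output schema.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{name}" for family, names in FAMILIES for name in names
)

FAMILY_SIZES: dict[str, int] = {family: len(names) for family, names in FAMILIES}

#: Shape / first-order / texture category of each feature.
FEATURE_CATEGORY: dict[str, str] = {
    name: (
        "shape"
        if name.startswith("shape_")
        else "first-order"
        if name.startswith("firstorder_")
        else "texture"
    )
    for name in FEATURE_NAMES
}


@dataclass
class FeatureVector:
    """The 85 named feature values of one ROI plus extraction provenance."""

    values: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError(
                f"feature schema mismatch: expected the frozen {len(FEATURE_NAMES)}-"
                f"name schema, got {len(self.values)} names"
            )

    def __len__(self) -> int:
        return len(self.values)


def extract_all(
    image: SequenceImage,
    delineation: Delineation,
    config=None,
) -> FeatureVector:
    """Extract the full 85-feature vector for one ROI on one sequence.

    ``config`` may be any object with a ``bin_width`` attribute (e.g. a
    RunConfig); the default bin width is 20 signal units.  ADC pixel values
    (stored in 10^-3 mm^2/s) are rescaled to 10^-6 mm^2/s before use so the
    absolute bin width spans the physiological range.  Pixels flagged
    missing (NaN, e.g. non-positive diffusion signal) are excluded from
    intensity and texture computation; shape always uses the full mask.
    Degenerate sub-computations yield flagged missing values (NaN), never
    dropped columns.
    """
    check_congruent(image, delineation)
    bin_width = float(getattr(config, "bin_width", 20.0) or 20.0)

    mask = delineation.mask
    pixels = image.pixels.astype(float)
    if image.sequence_label == "ADC":
        pixels = pixels * ADC_DISCRETIZATION_SCALE

    values: dict[str, float] = {}
    shape_vals = compute_shape(mask, image.spacing)
    for name in SHAPE_FEATURE_NAMES:
        values[f"shape_{name}"] = shape_vals[name]

    finite = np.isfinite(pixels)
    intensity_mask = mask & finite
    if intensity_mask.sum() == 0:
        for family, names in FAMILIES[1:]:
            for name in names:
                values[f"{family}_{name}"] = np.nan
        # Npix counts the delineated pixels even if all values are missing
        values["firstorder_Npix"] = float(mask.sum())
        return FeatureVector(values=values, provenance={"bin_width": bin_width})

    # Values below the absolute-discretization anchor (negative, e.g. noisy
    # ADC) are binned into the first bin; raw statistics keep them as-is.
    roi_raw = pixels[intensity_mask]
    disc = discretize(np.clip(pixels, 0.0, None), bin_width, mask=intensity_mask)

    fo = compute_first_order(roi_raw, disc)
    for name in FIRSTORDER_FEATURE_NAMES:
        values[f"firstorder_{name}"] = fo[name]
    values["firstorder_Npix"] = float(mask.sum())

    single_pixel = intensity_mask.sum() < 2
    if single_pixel:
        for family in ("glcm", "glszm", "glrlm", "ngtdm"):
            for name in dict(FAMILIES)[family]:
                values[f"{family}_{name}"] = np.nan
    else:
        glcm = glcm_features(build_glcm(disc))
        for name in GLCM_FEATURE_NAMES:
            values[f"glcm_{name}"] = glcm[name]
        glszm = glszm_features(build_glszm(disc))
        for name in GLSZM_FEATURE_NAMES:
            values[f"glszm_{name}"] = glszm[name]
        glrlm = glrlm_features(build_glrlm(disc))
        for name in GLRLM_FEATURE_NAMES:
            values[f"glrlm_{name}"] = glrlm[name]
        ngtdm = ngtdm_features(build_ngtdm(disc))
        for name in NGTDM_FEATURE_NAMES:
            values[f"ngtdm_{name}"] = ngtdm[name]

    provenance = {
        "bin_width": bin_width,
        "glcm_distance": 1,
        "directions": list(ANGLES_2D),
        "zone_connectivity": 8,
        "direction_aggregation": "merged (counts summed before normalisation)",
        "adc_rescale": ADC_DISCRETIZATION_SCALE
        if image.sequence_label == "ADC"
        else None,
    }
    return FeatureVector(values=values, provenance=provenance)


__all__ = [
    "ANGLES_2D",
    "FAMILIES",
    "FAMILY_SIZES",
    "FEATURE_CATEGORY",
    "FEATURE_NAMES",
    "FeatureVector",
    "TextureMatrix",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_ngtdm",
    "compute_first_order",
    "compute_shape",
    "extract_all",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]
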