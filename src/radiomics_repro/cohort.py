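"""Synthetic multi-sequence MRI cohort with known reader variability.

The generator emulates the design of a two-reader lacrimal-gland study:
``n_patients`` patients x 2 glands x 6 sequence contrasts, with three
delineations per ROI (L1 by reader 1; L2.1 and L2.2 by reader 2, whose
two sessions share a reader offset and differ only by a smaller
intra-reader deformation).  Each gland is an ellipse filled with a
spatially correlated Gaussian random texture, mapped through a per-sequence
affine contrast transform plus additive Gaussian noise.  The diffusion
sequence is synthesised as a (b0, b1000) signal pair consistent with a
smooth per-pixel ADC field, so the ADC map is obtained by actually running
:func:`radiomics_repro.preprocess.compute_adc` on noisy signals.

Delineations are shared between the two contrasts reconstructed from one
DIXON acquisition (in-phase/water T2 pair, and the post-contrast T1 pair)
and drawn independently for the other acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import SEQUENCE_LABELS, Delineation, SequenceImage
from .preprocess import compute_adc

_STRUCT8 = np.ones((3, 3), dtype=bool)

#: Sequences delineated together (one acquisition -> one set of readings).
ACQUISITION_GROUPS: tuple[tuple[str, ...], ...] = (
    ("T1",),
    ("ADC",),
    ("ipDIXON_T2", "wDIXON_T2"),
    ("PC_ipDIXON_T1", "PC_wDIXON_T1"),
)

#: Per-sequence affine contrast transform and noise: signal inside the
#: gland is offset + scale * texture_field + N(0, noise_sd).  The
#: diffusion entry parameterises the b0 signal; ADC noise then follows
#: from the signal noise through the log-ratio, making the ADC map the
#: noisiest contrast, as is typical clinically.
DEFAULT_CONTRASTS: dict[str, tuple[float, float, float]] = {
    "T1": (180.0, 40.0, 10.0),
    "ADC": (400.0, 60.0, 25.0),  # applies to the b0 signal (DWI SNR ~16)
    "ipDIXON_T2": (260.0, 60.0, 8.0),
    "wDIXON_T2": (300.0, 70.0, 6.0),
    "PC_ipDIXON_T1": (240.0, 55.0, 8.0),
    "PC_wDIXON_T1": (260.0, 60.0, 8.0),
}


@dataclass
class CohortSpec:
    """Design parameters of a synthetic cohort.

    Defaults reproduce the study design: 37 patients x 2 glands x 6
    sequences = 444 ROIs per reading.  Perturbation magnitudes are RMS
    radial boundary displacements in pixels; the intra-reader magnitude
    must not exceed the inter-reader one.
    """

    n_patients: int = 37
    glands_per_patient: int = 2
    sequence_labels: tuple[str, ...] = SEQUENCE_LABELS
    image_size: tuple[int, int] = (96, 96)
    spacing_mm: tuple[float, float] = (0.5, 0.5)
    gland_axes_range: tuple[float, float] = (7.0, 15.0)
    #: upper bound (pixels RMS) of the per-gland anatomical boundary
    #: irregularity applied to the truth ellipse; real glands and lesions
    #: differ in shape irregularity, which gives irregularity-type shape
    #: features (Solidity, Eccentricity, ...) between-subject variance
    truth_irregularity: float = 3.0
    contrasts: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRASTS)
    )
    texture_corr_length: float = 2.0
    #: relative SD of the per-gland tissue-intensity factor (biological
    #: between-subject heterogeneity; without it every gland would share
    #: one intensity distribution and agreement statistics degenerate)
    gland_intensity_jitter: float = 0.15
    inter_reader_perturb: float = 2.0
    intra_reader_perturb: float = 0.6
    b_values: tuple[float, float] = (0.0, 1000.0)
    adc_range: tuple[float, float] = (0.8, 1.8)  # 10^-3 mm^2/s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.intra_reader_perturb > self.inter_reader_perturb:
            raise ValueError(
                "intra_reader_perturb must not exceed inter_reader_perturb"
            )
        unknown = set(self.sequence_labels) - set(SEQUENCE_LABELS)
        if unknown:
            raise ValueError(f"unknown sequence labels: {sorted(unknown)}")


@dataclass
class SyntheticCase:
    """One gland: its six sequence images, 3 delineations each, and truth."""

    patient_id: str
    side: str
    images: dict[str, SequenceImage]
    delineations: dict[str, list[Delineation]]
    truth_mask: np.ndarray
    dwi_signals: tuple[np.ndarray, np.ndarray] | None
    adc_true: np.ndarray | None
    provenance: dict


def _smooth_field(shape, corr_length: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_length, mode="reflect")
    return (f - f.mean()) / f.std()


def _ellipse_mask(
    shape, center, semi_axes, angle_rad: float
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def perturb_mask(
    mask: np.ndarray,
    magnitude: float,
    rng: np.random.Generator,
    n_harmonics: int = 4,
    max_retries: int = 5,
) -> np.ndarray:
    """Smooth random radial deformation of a single-component binary mask.

    The boundary is displaced by a low-frequency periodic field
    ``delta(theta)`` (sum of ``n_harmonics`` random Fourier harmonics) with
    RMS amplitude ``magnitude`` pixels: a pixel at signed Euclidean
    distance ``s`` from the original boundary (positive outside) joins the
    perturbed mask when ``s <= delta(theta)``.  Holes are filled and the
    component nearest the original centroid is kept.  ``magnitude = 0``
    returns the input unchanged; a perturbation that would empty the mask
    is retried with damped magnitude and finally raises.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return mask.copy()

    dist_out = ndimage.distance_transform_edt(~mask)
    dist_in = ndimage.distance_transform_edt(mask)
    signed = dist_out - dist_in  # >0 outside, <0 inside
    r_cent, c_cent = ndimage.center_of_mass(mask)
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    theta = np.arctan2(rr - r_cent, cc - c_cent)

    mag = float(magnitude)
    for _ in range(max_retries):
        coeffs = rng.standard_normal(2 * n_harmonics) * mag / np.sqrt(n_harmonics)
        delta = np.zeros(mask.shape)
        for k in range(1, n_harmonics + 1):
            delta += coeffs[2 * k - 2] * np.cos(k * theta)
            delta += coeffs[2 * k - 1] * np.sin(k * theta)
        new = signed <= delta
        new = ndimage.binary_fill_holes(new)
        labelled, n_comp = ndimage.label(new, structure=_STRUCT8)
        if n_comp >= 1:
            if n_comp > 1:
                lab_at_cent = labelled[int(round(r_cent)), int(round(c_cent))]
                if lab_at_cent == 0:
                    sizes = np.bincount(labelled.ravel())[1:]
                    lab_at_cent = int(np.argmax(sizes)) + 1
                new = labelled == lab_at_cent
            if new.sum() >= 1:
                return new
        mag *= 0.5
    raise RuntimeError(
        f"perturbation emptied the mask after {max_retries} damped retries"
    )


def _reader_masks(
    truth: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> list[Delineation]:
    """The three reading sessions for one acquisition's geometry."""
    l1 = perturb_mask(truth, spec.inter_reader_perturb, rng)
    reader2 = perturb_mask(truth, spec.inter_reader_perturb, rng)
    l21 = perturb_mask(reader2, spec.intra_reader_perturb, rng)
    l22 = perturb_mask(reader2, spec.intra_reader_perturb, rng)
    return [
        Delineation(mask=l1, reading="L1"),
        Delineation(mask=l21, reading="L2.1"),
        Delineation(mask=l22, reading="L2.2"),
    ]


def _generate_case(
    patient_id: str, side: str, spec: CohortSpec, rng: np.random.Generator
) -> SyntheticCase:
    h, w = spec.image_size
    lo, hi = spec.gland_axes_range
    axes = rng.uniform(lo, hi, size=2)
    margin = axes.max() + 3.0 * spec.inter_reader_perturb + 2.0
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"ellipse with semi-axes {axes} plus perturbation margin does not "
            f"fit inside a {h}x{w} image"
        )
    center = (
        h / 2 + rng.uniform(-4, 4),
        w / 2 + rng.uniform(-4, 4),
    )
    angle = rng.uniform(0, np.pi)
    truth = _ellipse_mask((h, w), center, axes, angle)
    irregularity = rng.uniform(0.0, spec.truth_irregularity)
    if irregularity > 0:
        truth = perturb_mask(truth, irregularity, rng)

    # shared anatomy: one texture field per gland, plus biological
    # intensity factor distinguishing subjects
    anatomy = _smooth_field((h, w), spec.texture_corr_length, rng)
    tissue_factor = 1.0 + spec.gland_intensity_jitter * rng.standard_normal()
    soft = ndimage.gaussian_filter(truth.astype(float), sigma=1.0)

    images: dict[str, SequenceImage] = {}
    delineations: dict[str, list[Delineation]] = {}
    dwi_signals = None
    adc_true = None

    for group in ACQUISITION_GROUPS:
        group_labels = [s for s in group if s in spec.sequence_labels]
        if not group_labels:
            continue
        readings = _reader_masks(truth, spec, rng)
        for label in group_labels:
            offset, scale, noise_sd = spec.contrasts[label]
            offset = offset * tissue_factor
            background = 0.3 * offset
            clean = background + (offset - background) * soft + scale * anatomy
            if label == "ADC":
                # smooth true ADC field in [adc_lo, adc_hi] x 10^-3 mm^2/s
                adc_field = _smooth_field((h, w), spec.texture_corr_length, rng)
                lo_a, hi_a = spec.adc_range
                adc_true = lo_a + (hi_a - lo_a) / (
                    1.0 + np.exp(-adc_field)
                )
                b_low, b_high = spec.b_values
                s0 = np.clip(clean, 1.0, None)
                s1 = s0 * np.exp(-(b_high - b_low) * adc_true * 1e-3)
                s0_noisy = np.clip(s0 + noise_sd * rng.standard_normal((h, w)), 0.05, None)
                s1_noisy = np.clip(s1 + noise_sd * rng.standard_normal((h, w)), 0.05, None)
                dwi_signals = (s0_noisy, s1_noisy)
                b0_img = SequenceImage(
                    pixels=s0_noisy,
                    spacing=spec.spacing_mm,
                    sequence_label="ADC",  # carrier label; signals are b0/b1000
                    patient_id=patient_id,
                    side=side,
                )
                b1_img = SequenceImage(
                    pixels=s1_noisy,
                    spacing=spec.spacing_mm,
                    sequence_label="ADC",
                    patient_id=patient_id,
                    side=side,
                )
                images[label] = compute_adc(b0_img, b1_img, b_low, b_high)
            else:
                noisy = np.clip(
                    clean + noise_sd * rng.standard_normal((h, w)), 0.0, None
                )
                images[label] = SequenceImage(
                    pixels=noisy,
                    spacing=spec.spacing_mm,
                    sequence_label=label,
                    patient_id=patient_id,
                    side=side,
                )
            delineations[label] = [
                Delineation(mask=d.mask.copy(), reading=d.reading)
                for d in readings
            ]

    return SyntheticCase(
        patient_id=patient_id,
        side=side,
        images=images,
        delineations=delineations,
        truth_mask=truth,
        dwi_signals=dwi_signals,
        adc_true=adc_true,
        provenance={
            "semi_axes": axes.tolist(),
            "center": [float(center[0]), float(center[1])],
            "angle_rad": float(angle),
            "tissue_factor": float(tissue_factor),
        },
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticCase]:
    """Generate the full cohort, bit-reproducibly for a fixed seed."""
    sides = ("left", "right")
    n_cases = spec.n_patients * spec.glands_per_patient
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(n_cases)
    cases = []
    k = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p + 1:03d}"
        for g in range(spec.glands_per_patient):
            rng = np.random.default_rng(seeds[k])
            cases.append(_generate_case(patient_id, sides[g % 2], spec, rng))
            k += 1
    return cases
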