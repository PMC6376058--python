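"""Reading and writing images, masks and feature tables.

Images and masks are stored as NIfTI (one 2D slice as a 1-slice volume,
pixel spacing in the header); feature tables are long-format CSV keyed by
(patient_id, side, sequence, reading) with the frozen 85-column feature
schema.  File-name conventions carry the metadata:

* image: ``{patient}_{side}_{sequence}.nii.gz``
* mask:  ``{patient}_{side}_{sequence}_mask_{reading}.nii.gz`` with
  reading one of ``L1``, ``L2.1``, ``L2.2``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import READINGS, SEQUENCE_LABELS, Delineation, SequenceImage
from .features import FEATURE_NAMES

KEY_COLUMNS: tuple[str, ...] = ("patient_id", "side", "sequence", "reading")


def _nifti_name(patient_id: str, side: str, sequence: str) -> str:
    if "_" in patient_id or "_" in side:
        raise ValueError("patient_id and side must not contain underscores")
    return f"{patient_id}_{side}_{sequence}"


def write_image(image: SequenceImage, out_dir: str | Path) -> Path:
    """Write one sequence image as a 1-slice NIfTI volume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / (
        _nifti_name(image.patient_id, image.side, image.sequence_label) + ".nii.gz"
    )
    affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
    vol = image.pixels.astype(np.float64)[:, :, None]
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    return path


def write_mask(
    delineation: Delineation,
    image: SequenceImage,
    out_dir: str | Path,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _nifti_name(image.patient_id, image.side, image.sequence_label)
    path = out_dir / f"{stem}_mask_{delineation.reading}.nii.gz"
    affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
    vol = delineation.mask.astype(np.uint8)[:, :, None]
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    return path


def _strip_nii(name: str) -> str:
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    raise ValueError(f"not a NIfTI file name: {name}")


def _parse_image_name(path: Path) -> tuple[str, str, str]:
    stem = _strip_nii(path.name)
    parts = stem.split("_")
    if len(parts) < 3:
        raise ValueError(f"cannot parse case metadata from file name {path.name!r}")
    patient_id, side = parts[0], parts[1]
    sequence = "_".join(parts[2:])
    if sequence not in SEQUENCE_LABELS:
        raise ValueError(f"unknown sequence label {sequence!r} in {path.name!r}")
    return patient_id, side, sequence


def _parse_reading(path: Path) -> str:
    stem = _strip_nii(path.name)
    for reading in READINGS:
        if stem.endswith(f"_mask_{reading}"):
            return reading
    raise ValueError(
        f"mask file name {path.name!r} does not end in _mask_L1/_mask_L2.1/_mask_L2.2"
    )


def _load_slice(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(
                f"{path.name}: expected a 1-slice volume, got shape {data.shape}"
            )
        data = data[:, :, 0]
    elif data.ndim != 2:
        raise ValueError(f"{path.name}: unsupported dimensionality {data.ndim}")
    zooms = img.header.get_zooms()[:2]
    return np.asarray(data, dtype=float), (float(zooms[0]), float(zooms[1]))


def read_case(
    image_path: str | Path, mask_paths: list[str | Path]
) -> tuple[SequenceImage, list[Delineation]]:
    """Read one sequence image and its delineations.

    Spacing comes from the NIfTI header; masks are binarized (any nonzero
    pixel is foreground) and their reading labels taken from the file-name
    convention.  Grid mismatches and empty or multi-component masks raise.
    """
    image_path = Path(image_path)
    patient_id, side, sequence = _parse_image_name(image_path)
    pixels, spacing = _load_slice(image_path)
    image = SequenceImage(
        pixels=pixels,
        spacing=spacing,
        sequence_label=sequence,
        patient_id=patient_id,
        side=side,
    )
    delineations = []
    for mp in mask_paths:
        mp = Path(mp)
        reading = _parse_reading(mp)
        mask, _ = _load_slice(mp)
        mask_bool = mask != 0
        if mask_bool.shape != pixels.shape:
            raise ValueError(
                f"grid mismatch: image {pixels.shape} vs mask {mask_bool.shape} "
                f"({mp.name})"
            )
        delineations.append(Delineation(mask=mask_bool, reading=reading))
    return image, delineations


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format feature table as CSV.

    Columns are the four keys followed by the 85 features in schema order;
    values round-trip losslessly (17 significant digits).
    """
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing key column(s): {missing}")
    missing_feats = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing_feats:
        raise ValueError(
            f"missing {len(missing_feats)} feature column(s), "
            f"e.g. {missing_feats[:3]}"
        )
    ordered = table[list(KEY_COLUMNS) + list(FEATURE_NAMES)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing key column(s): {missing}")
    missing_feats = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing_feats:
        raise ValueError(
            f"missing {len(missing_feats)} feature column(s), "
            f"e.g. {missing_feats[:3]}"
        )
    return table[list(KEY_COLUMNS) + list(FEATURE_NAMES)]
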