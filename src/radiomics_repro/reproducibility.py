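"""Agreement statistics and reproducibility-based feature selection.

For every (feature, sequence) pair the three pairwise reading combinations
(L1/L2.1, L1/L2.2, L2.1/L2.2) are scored with the two-way mixed-model
intraclass correlation, absolute agreement, average-measures form
(McGraw-Wong ICC(A,k), k = 2 raters), and the intra-reader pair
(L2.1/L2.2) additionally with Lin's concordance correlation coefficient.
A pair is *reproducible* when all three ICCs reach ``icc_threshold`` (0.8
by default), the CCC reaches ``ccc_threshold`` (0.9 by default) and no
input value is flagged missing.

The ICC is written out from the two-way ANOVA mean squares (rows =
subjects/ROIs, columns = readings) so no statistics package is
load-bearing::

    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

It may be negative and is reported as computed (never floored at 0).
Lin's CCC uses population (divisor n) moments::

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import READINGS
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: the three reading pairings scored with the ICC
ICC_PAIRINGS: tuple[tuple[str, str], ...] = (
    ("L1", "L2.1"),
    ("L1", "L2.2"),
    ("L2.1", "L2.2"),
)

REPRO_COLUMNS: tuple[str, ...] = (
    "feature",
    "sequence",
    "icc_L1_L21",
    "icc_L1_L22",
    "icc_L21_L22",
    "ccc_L21_L22",
    "n_subjects",
    "has_missing",
    "reproducible",
)


def icc_absolute_average(x: np.ndarray, y: np.ndarray) -> float:
    """McGraw-Wong ICC(A,k) for two readings of n subjects.

    Requires n >= 3 complete pairs; a degenerate design (zero denominator,
    e.g. both readings constant) is flagged missing (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        return float("nan")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ms_rows = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = ms_rows + (ms_cols - ms_err) / n
    if denom == 0:
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 2:
        raise ValueError(f"need at least 2 paired observations, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        return float("nan")
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    if vx == 0 and vy == 0:
        return float("nan")
    sxy = ((x - mx) * (y - my)).mean()
    return float(2.0 * sxy / (vx + vy + (mx - my) ** 2))


def _reading_pivot(seq_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-reading frames indexed by (patient_id, side), complete ROIs only."""
    by_reading = {
        reading: grp.set_index(["patient_id", "side"])[list(FEATURE_NAMES)]
        for reading, grp in seq_table.groupby("reading")
    }
    missing_readings = [r for r in READINGS if r not in by_reading]
    if missing_readings:
        raise ValueError(f"reading(s) {missing_readings} absent from table")
    common = by_reading["L1"].index
    for reading in READINGS[1:]:
        common = common.intersection(by_reading[reading].index)
    for reading in READINGS:
        dropped = by_reading[reading].index.difference(common)
        if len(dropped):
            logger.warning(
                "dropping %d ROI(s) missing from some reading: %s",
                len(dropped),
                list(dropped[:5]),
            )
        by_reading[reading] = by_reading[reading].loc[common].sort_index()
    return by_reading


def select_reproducible(
    feature_table: pd.DataFrame,
    icc_threshold: float = 0.8,
    ccc_threshold: float = 0.9,
) -> pd.DataFrame:
    """Score and flag every (feature, sequence) pair.

    ``feature_table`` is the long table keyed by (patient_id, side,
    sequence, reading).  All ROIs of a sequence (both glands, all
    patients) are pooled as subjects.  Returns one row per (feature,
    sequence) with the three ICCs, the CCC, the number of complete
    subjects, and the reproducible flag.  ROIs missing a reading are
    dropped from all pairings with a logged warning; a flagged-missing
    feature value in any reading disqualifies the pair from being
    reproducible.
    """
    records = []
    for sequence, seq_table in feature_table.groupby("sequence", sort=True):
        by_reading = _reading_pivot(seq_table)
        arrays = {r: by_reading[r].to_numpy(dtype=float) for r in READINGS}
        n_subjects = arrays["L1"].shape[0]
        for j, feature in enumerate(FEATURE_NAMES):
            cols = {r: arrays[r][:, j] for r in READINGS}
            has_missing = any(~np.isfinite(v).all() for v in cols.values())
            complete = np.ones(n_subjects, dtype=bool)
            for v in cols.values():
                complete &= np.isfinite(v)
            n_complete = int(complete.sum())
            iccs = {}
            for a, b in ICC_PAIRINGS:
                key = f"icc_{a.replace('.', '')}_{b.replace('.', '')}"
                if n_complete >= 3:
                    iccs[key] = icc_absolute_average(
                        cols[a][complete], cols[b][complete]
                    )
                else:
                    iccs[key] = float("nan")
            if n_complete >= 2:
                ccc = lin_ccc(cols["L2.1"][complete], cols["L2.2"][complete])
            else:
                ccc = float("nan")
            icc_values = np.array(list(iccs.values()))
            reproducible = bool(
                not has_missing
                and np.all(np.isfinite(icc_values))
                and np.isfinite(ccc)
                and icc_values.min() >= icc_threshold
                and ccc >= ccc_threshold
            )
            records.append(
                {
                    "feature": feature,
                    "sequence": sequence,
                    "icc_L1_L21": iccs["icc_L1_L21"],
                    "icc_L1_L22": iccs["icc_L1_L22"],
                    "icc_L21_L22": iccs["icc_L21_L22"],
                    "ccc_L21_L22": ccc,
                    "n_subjects": n_complete,
                    "has_missing": bool(has_missing),
                    "reproducible": reproducible,
                }
            )
    return pd.DataFrame.from_records(records, columns=list(REPRO_COLUMNS))


def apply_thresholds(
    repro: pd.DataFrame, icc_threshold: float, ccc_threshold: float
) -> pd.Series:
    """Recompute the reproducible flag from already-computed ICC/CCC values.

    Used by the threshold sweep so the agreement statistics are computed
    once and thresholding stays a cheap filter.
    """
    iccs = repro[["icc_L1_L21", "icc_L1_L22", "icc_L21_L22"]]
    ok = (
        ~repro["has_missing"]
        & iccs.notna().all(axis=1)
        & repro["ccc_L21_L22"].notna()
        & (iccs.min(axis=1) >= icc_threshold)
        & (repro["ccc_L21_L22"] >= ccc_threshold)
    )
    return ok
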