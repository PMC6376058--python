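"""Texture features computed from grey-level matrices.

Formula conventions (written out because several Table-style feature names
are toolbox-specific rather than standardised):

GLCM — on the merged, symmetric, normalised matrix p(i, j) with marginals
p_x(i) = sum_j p(i, j), means mu_x and standard deviations sigma_x (equal
to the y-quantities by symmetry), diagonal distributions
p_{x+y}(k) = sum_{i+j=k} p(i, j) and p_{x-y}(k) = sum_{|i-j|=k} p(i, j):

* Agreement: Cohen's kappa of the matrix against its marginals,
  (sum_i p(i,i) - sum_i p_x(i) p_y(i)) / (1 - sum_i p_x(i) p_y(i)).
* Correlation 1: sum_{ij} (i - mu_x)(j - mu_y) p(i,j) / (sigma_x sigma_y);
  Correlation 2: (sum_{ij} i j p(i,j) - mu_x mu_y) / (sigma_x sigma_y).
  On a symmetric matrix the two parameterizations coincide analytically;
  both are kept because the feature schema is frozen.
* Homogeneity 1 = inverse difference  sum p / (1 + |i-j|);
  Homogeneity 2 = inverse difference moment  sum p / (1 + (i-j)^2), which
  the schema also lists as IDM.  IDMN normalises the difference by the
  number of grey levels:  sum p / (1 + ((i-j)/Ng)^2).
* Sum Mean = Sum Average / 2 (mean of (i+j)/2 under p_{x+y}).
* Variance 1 = joint grey-level variance  sum (i - mu_x)^2 p(i,j);
  Variance 2 = difference variance, the variance of p_{x-y}.

GLRLM / GLSZM — IBSI emphases on the normalised run (zone) matrix, with
grey level i, run length (zone size) j and N_s total runs (zones);
non-uniformities use counts: GLN = sum_i (sum_j R_ij)^2 / N_s, and
ZP = N_s / N_pixels.  For the direction-merged run matrix the run
percentage divides by pixels x directions (RP = N_s / (N_pix * 4)), so a
fully fragmented ROI scores exactly 1.

NGTDM — Amadasun-King statistics from the occupancy probabilities p_i and
summed grey-tone differences s_i; Coarseness is capped at 10^6 when its
denominator vanishes.

Degenerate inputs (empty matrix, zero variance where a variance is
required) yield flagged missing values (NaN), never silent zeros.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrix

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "Agreement",
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation1",
    "Correlation2",
    "DifferenceEntropy",
    "Dissimilarity",
    "Homogeneity1",
    "Homogeneity2",
    "IMC1",
    "IMC2",
    "IDM",
    "IDMN",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumMean",
    "SumVariance",
    "Variance1",
    "Variance2",
)

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "GLV",
    "GLN",
    "HGLRE",
    "LRE",
    "LRHGLE",
    "LRLGLE",
    "LGLRE",
    "RLN",
    "RP",
    "RV",
    "SRE",
    "SRHGLE",
    "SRLGLE",
)

GLSZM_FEATURE_NAMES: tuple[str, ...] = (
    "GLN",
    "GLV",
    "HGLZE",
    "LAE",
    "LAHGLE",
    "LALGLE",
    "LGLZE",
    "ZSN",
    "SAE",
    "SAHGLE",
    "SALGLE",
    "ZP",
    "ZV",
)

NGTDM_FEATURE_NAMES: tuple[str, ...] = (
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
)

COARSENESS_CAP = 1e6


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    if tm.kind != "GLCM":
        raise ValueError(f"expected a GLCM, got {tm.kind}")
    if tm.matrix.sum() == 0:
        return {name: np.nan for name in GLCM_FEATURE_NAMES}
    p = tm.normalized
    ng = tm.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())
    sigma_xy = np.sqrt(var_x * var_y)

    # diagonal distributions
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(ksum.size)
    kdiff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(kdiff.size)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    autocorr = float((ii * jj * p).sum())
    sum_average = float((ksum * p_sum).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    homogeneity1 = float((p / (1.0 + np.abs(ii - jj))).sum())
    homogeneity2 = float((p / (1.0 + (ii - jj) ** 2)).sum())
    idmn = float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum())
    off = ii != jj
    inverse_variance = float((p[off] / (ii[off] - jj[off]) ** 2).sum())

    joint_entropy = _entropy2(p.ravel())
    # information measures of correlation
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxpy = np.log2(np.outer(px, py))
    mask_pos = (p > 0) & np.isfinite(log_pxpy)
    hxy1 = float(-(p[mask_pos] * log_pxpy[mask_pos]).sum())
    outer = np.outer(px, py)
    pos = outer > 0
    hxy2 = float(-(outer[pos] * np.log2(outer[pos])).sum())
    hx = _entropy2(px)
    hy = _entropy2(py)
    denom = max(hx, hy)
    imc1 = (joint_entropy - hxy1) / denom if denom > 0 else np.nan
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    po = float(np.trace(p))
    pe = float((px * py).sum())
    agreement = (po - pe) / (1.0 - pe) if pe < 1.0 else np.nan

    if sigma_xy > 0:
        correlation1 = float(((ii - mu_x) * (jj - mu_y) * p).sum()) / sigma_xy
        correlation2 = (autocorr - mu_x * mu_y) / sigma_xy
    else:
        correlation1 = np.nan
        correlation2 = np.nan

    mu_diff = float((kdiff * p_diff).sum())
    return {
        "Agreement": agreement,
        "Autocorrelation": autocorr,
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation1": correlation1,
        "Correlation2": correlation2,
        "DifferenceEntropy": _entropy2(p_diff),
        "Dissimilarity": dissimilarity,
        "Homogeneity1": homogeneity1,
        "Homogeneity2": homogeneity2,
        "IMC1": imc1,
        "IMC2": imc2,
        "IDM": homogeneity2,
        "IDMN": idmn,
        "InverseVariance": inverse_variance,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": joint_entropy,
        "MaximumProbability": float(p.max()),
        "SumAverage": sum_average,
        "SumEntropy": _entropy2(p_sum),
        "SumMean": sum_average / 2.0,
        "SumVariance": float(((ksum - sum_average) ** 2 * p_sum).sum()),
        "Variance1": float(((ii - mu_x) ** 2 * p).sum()),
        "Variance2": float(((kdiff - mu_diff) ** 2 * p_diff).sum()),
    }


def _run_zone_features(tm: TextureMatrix, names: dict[str, str]) -> dict[str, float]:
    """Shared IBSI emphases for run-length and size-zone matrices.

    ``names`` maps generic keys to the family's feature names.
    """
    counts = tm.matrix
    ns = counts.sum()
    if ns == 0:
        return {v: np.nan for v in names.values()}
    pct_divisor = tm.n_roi_pixels * (len(tm.directions) if tm.directions else 1)
    p = counts / ns
    ng, nr = counts.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nr + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((i * p_i).sum())
    mu_j = float((j * p_j).sum())
    out = {
        "short": float((p / jj**2).sum()),
        "long": float((p * jj**2).sum()),
        "gln": float((counts.sum(axis=1) ** 2).sum() / ns),
        "len_n": float((counts.sum(axis=0) ** 2).sum() / ns),
        "pct": float(ns / pct_divisor),
        "glv": float((p * (ii - mu_i) ** 2).sum()),
        "len_v": float((p * (jj - mu_j) ** 2).sum()),
        "lgl": float((p / ii**2).sum()),
        "hgl": float((p * ii**2).sum()),
        "short_lgl": float((p / (ii**2 * jj**2)).sum()),
        "short_hgl": float((p * ii**2 / jj**2).sum()),
        "long_lgl": float((p * jj**2 / ii**2).sum()),
        "long_hgl": float((p * ii**2 * jj**2).sum()),
    }
    return {v: out[k] for k, v in names.items()}


_GLRLM_MAP = {
    "glv": "GLV",
    "gln": "GLN",
    "hgl": "HGLRE",
    "long": "LRE",
    "long_hgl": "LRHGLE",
    "long_lgl": "LRLGLE",
    "lgl": "LGLRE",
    "len_n": "RLN",
    "pct": "RP",
    "len_v": "RV",
    "short": "SRE",
    "short_hgl": "SRHGLE",
    "short_lgl": "SRLGLE",
}

_GLSZM_MAP = {
    "gln": "GLN",
    "glv": "GLV",
    "hgl": "HGLZE",
    "long": "LAE",
    "long_hgl": "LAHGLE",
    "long_lgl": "LALGLE",
    "lgl": "LGLZE",
    "len_n": "ZSN",
    "short": "SAE",
    "short_hgl": "SAHGLE",
    "short_lgl": "SALGLE",
    "pct": "ZP",
    "len_v": "ZV",
}


def glrlm_features(tm: TextureMatrix) -> dict[str, float]:
    if tm.kind != "GLRLM":
        raise ValueError(f"expected a GLRLM, got {tm.kind}")
    return _run_zone_features(tm, _GLRLM_MAP)


def glszm_features(tm: TextureMatrix) -> dict[str, float]:
    if tm.kind != "GLSZM":
        raise ValueError(f"expected a GLSZM, got {tm.kind}")
    return _run_zone_features(tm, _GLSZM_MAP)


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    if tm.kind != "NGTDM":
        raise ValueError(f"expected an NGTDM, got {tm.kind}")
    n_i = tm.matrix[:, 0]
    s_i = tm.matrix[:, 1]
    n_valid = n_i.sum()
    if n_valid == 0:
        return {name: np.nan for name in NGTDM_FEATURE_NAMES}
    p_i = n_i / n_valid
    levels = np.arange(1, tm.n_levels + 1, dtype=float)
    occupied = p_i > 0
    ngp = int(occupied.sum())
    i_occ = levels[occupied]
    p_occ = p_i[occupied]
    s_occ = s_i[occupied]

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ngp > 1:
        di = i_occ[:, None] - i_occ[None, :]
        pp = p_occ[:, None] * p_occ[None, :]
        contrast = (
            float((pp * di**2).sum())
            / (ngp * (ngp - 1))
            * float(s_i.sum())
            / n_valid
        )
        busy_den = float(
            np.abs(i_occ[:, None] * p_occ[:, None] - i_occ[None, :] * p_occ[None, :]).sum()
        )
        busyness = ps / busy_den if busy_den > 0 else 0.0
        ps_pair = p_occ[:, None] * s_occ[:, None] + p_occ[None, :] * s_occ[None, :]
        p_pair = p_occ[:, None] + p_occ[None, :]
        complexity = float((np.abs(di) * ps_pair / p_pair).sum()) / n_valid
        s_total = float(s_i.sum())
        strength = (
            float((p_pair * di**2).sum()) / s_total if s_total > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
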