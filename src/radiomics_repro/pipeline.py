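"""End-to-end orchestration: simulate, extract, select, cluster, report.

``run_pipeline`` chains the stages on a synthetic cohort and writes all
artifacts (features, reproducibility records, cluster assignments, the
cross-sequence overlap summary and the ICC/CCC threshold sweep) as CSV
plus a provenance JSON.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SyntheticCase, generate_cohort
from .config import RunConfig
from .features import FEATURE_CATEGORY, FEATURE_NAMES, extract_all
from .io import KEY_COLUMNS, write_feature_table
from .redundancy import (
    cluster_features,
    cluster_sequence,
    pooled_cluster,
    spearman_matrix,
)
from .reproducibility import apply_thresholds, select_reproducible

logger = logging.getLogger(__name__)

DEFAULT_ICC_GRID: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_CCC_GRID: tuple[float, ...] = (
    0.5,
    0.55,
    0.6,
    0.65,
    0.7,
    0.75,
    0.8,
    0.85,
    0.9,
    0.95,
)


def extract_cohort_features(
    cases: list[SyntheticCase], config: RunConfig | None = None
) -> pd.DataFrame:
    """Long feature table over every (case, sequence, reading)."""
    rows = []
    for case in cases:
        for label, image in case.images.items():
            for delineation in case.delineations[label]:
                fv = extract_all(image, delineation, config)
                row = {
                    "patient_id": case.patient_id,
                    "side": case.side,
                    "sequence": label,
                    "reading": delineation.reading,
                }
                row.update(fv.values)
                rows.append(row)
    return pd.DataFrame(rows, columns=list(KEY_COLUMNS) + list(FEATURE_NAMES))


def overlap_summary(repro: pd.DataFrame) -> pd.DataFrame:
    """Exact subset-membership counts of reproducible features.

    For each non-empty subset of sequences, the number of features
    reproducible in *exactly* that subset (UpSet semantics), split by
    feature category.  Subset counts partition the features reproducible
    in at least one sequence.
    """
    flagged = repro[repro["reproducible"]]
    rows = []
    by_feature: dict[str, tuple[str, ...]] = {}
    for feature, grp in flagged.groupby("feature"):
        by_feature[feature] = tuple(sorted(grp["sequence"].unique()))
    subset_counts: dict[tuple[str, ...], dict[str, int]] = {}
    for feature, subset in by_feature.items():
        cat = FEATURE_CATEGORY[feature]
        subset_counts.setdefault(subset, {}).setdefault(cat, 0)
        subset_counts[subset][cat] += 1
    for subset in sorted(subset_counts, key=lambda s: (len(s), s)):
        for cat, count in sorted(subset_counts[subset].items()):
            rows.append(
                {
                    "subset": "+".join(subset),
                    "n_sequences": len(subset),
                    "category": cat,
                    "count": count,
                }
            )
    return pd.DataFrame(
        rows, columns=["subset", "n_sequences", "category", "count"]
    )


def marginal_counts(repro: pd.DataFrame) -> pd.DataFrame:
    """Reproducible-feature count per sequence."""
    return (
        repro.groupby("sequence")["reproducible"]
        .sum()
        .astype(int)
        .rename("n_reproducible")
        .reset_index()
    )


def threshold_sweep(
    feature_table: pd.DataFrame,
    icc_values: tuple[float, ...] = DEFAULT_ICC_GRID,
    ccc_values: tuple[float, ...] = DEFAULT_CCC_GRID,
    spearman_cutoff: float = 0.9,
    reading: str = "L1",
    repro: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sequence feature and cluster counts over an ICC x CCC grid.

    The agreement statistics are computed once and every grid cell is a
    cheap re-thresholding; clustering uses one Spearman matrix per
    sequence, subset per cell.
    """
    if repro is None:
        repro = select_reproducible(feature_table)
    sequences = sorted(feature_table["sequence"].unique())
    matrices = {}
    for sequence in sequences:
        ref = feature_table[
            (feature_table["sequence"] == sequence)
            & (feature_table["reading"] == reading)
        ].set_index(["patient_id", "side"])[list(FEATURE_NAMES)]
        matrices[sequence] = spearman_matrix(ref)
    rows = []
    for icc_thr, ccc_thr in itertools.product(icc_values, ccc_values):
        flags = apply_thresholds(repro, icc_thr, ccc_thr)
        selected = repro[flags]
        for sequence in sequences:
            feats = selected[selected["sequence"] == sequence]["feature"].tolist()
            if feats:
                sub = matrices[sequence].loc[feats, feats]
                n_clusters = cluster_features(sub, cutoff=spearman_cutoff).n_clusters
            else:
                n_clusters = 0
            rows.append(
                {
                    "icc_threshold": icc_thr,
                    "ccc_threshold": ccc_thr,
                    "sequence": sequence,
                    "n_reproducible": len(feats),
                    "n_clusters": n_clusters,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "icc_threshold",
            "ccc_threshold",
            "sequence",
            "n_reproducible",
            "n_clusters",
        ],
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate, extract, select, cluster, sweep and report.

    Writes ``features.csv``, ``repro.csv``, ``clusters.csv``,
    ``overlap.csv``, ``sweep.csv`` and ``provenance.json`` into
    ``out_dir`` and returns their paths.  Idempotent for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    logger.info("stage=simulate n_patients=%d", config.cohort.n_patients)
    cases = generate_cohort(config.cohort)
    logger.info("stage=simulate done n_cases=%d", len(cases))

    table = extract_cohort_features(cases, config)
    paths["features"] = write_feature_table(table, out_dir / "features.csv")
    logger.info(
        "stage=extract rows=%d feature_values=%d",
        len(table),
        len(table) * len(FEATURE_NAMES),
    )

    repro = select_reproducible(
        table, config.icc_threshold, config.ccc_threshold
    )
    paths["repro"] = out_dir / "repro.csv"
    repro.to_csv(paths["repro"], index=False, float_format="%.17g")
    n_repro = int(repro["reproducible"].sum())
    logger.info("stage=select records=%d reproducible=%d", len(repro), n_repro)

    cluster_frames = []
    for sequence in sorted(table["sequence"].unique()):
        result = cluster_sequence(
            repro, table, sequence, cutoff=config.spearman_cutoff
        )
        frame = result.to_frame()
        if not frame.empty:
            frame.insert(0, "scope", sequence)
            frame["sequence"] = sequence
            cluster_frames.append(frame)
        logger.info(
            "stage=cluster sequence=%s n_items=%d n_clusters=%d",
            sequence,
            len(result.items),
            result.n_clusters,
        )
    pooled = pooled_cluster(repro, table, cutoff=config.spearman_cutoff)
    pooled_frame = pooled.to_frame()
    if not pooled_frame.empty:
        pooled_frame.insert(0, "scope", "pooled")
        cluster_frames.append(pooled_frame)
    logger.info(
        "stage=cluster scope=pooled n_items=%d n_clusters=%d",
        len(pooled.items),
        pooled.n_clusters,
    )
    clusters = (
        pd.concat(cluster_frames, ignore_index=True)
        if cluster_frames
        else pd.DataFrame(columns=["scope", "feature", "sequence", "cluster"])
    )
    paths["clusters"] = out_dir / "clusters.csv"
    clusters.to_csv(paths["clusters"], index=False)

    overlap = overlap_summary(repro)
    paths["overlap"] = out_dir / "overlap.csv"
    overlap.to_csv(paths["overlap"], index=False)
    n_any = int(overlap["count"].sum())
    logger.info("stage=report features_in_at_least_one_sequence=%d", n_any)

    sweep = threshold_sweep(
        table, spearman_cutoff=config.spearman_cutoff, repro=repro
    )
    paths["sweep"] = out_dir / "sweep.csv"
    sweep.to_csv(paths["sweep"], index=False)
    logger.info("stage=sweep cells=%d", len(sweep))

    provenance = {
        "config": json.loads(json.dumps(config.__dict__, default=lambda o: o.__dict__)),
        "seed": config.rng_seed,
        "n_cases": len(cases),
        "python": sys.version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    paths["provenance"] = out_dir / "provenance.json"
    paths["provenance"].write_text(json.dumps(provenance, indent=2, default=list))
    return paths
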