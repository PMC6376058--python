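"""Redundancy reduction: hierarchical clustering on Spearman correlation.

Two features are redundant when their Spearman rank correlation exceeds
the cutoff (0.9 by default).  Agglomerative clustering with distance
``d = 1 - rho`` and *complete* linkage, cut just below height
``1 - cutoff``, makes the redundancy statement literally true for every
within-cluster pair: all pairwise rho strictly above the cutoff.

Observation vectors are a feature's values across all ROIs of a single
reference reading (L1 by default), so reader variance never leaks into
the redundancy structure.  Signed correlation is used — anti-correlated
features are not merged — with ``absolute=True`` available as a switch.
Constant columns have undefined rank correlation; they are isolated into
singleton clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .features import FEATURE_NAMES


@dataclass
class ClusterResult:
    """Assignment of items to redundancy clusters.

    ``items`` are feature names (per-sequence clustering) or
    ``(feature, sequence)`` tuples (pooled clustering); ``assignment``
    maps each item to a 1-based cluster id.
    """

    items: list
    assignment: dict
    n_clusters: int
    linkage_matrix: np.ndarray | None = None
    #: the items that are leaves of ``linkage_matrix``, in leaf order
    linkage_items: list | None = None
    heights: np.ndarray | None = None
    method: str = "complete"
    cutoff: float = 0.9

    def clusters(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for item, cid in self.assignment.items():
            out.setdefault(cid, []).append(item)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for item in self.items:
            if isinstance(item, tuple):
                rows.append(
                    {
                        "feature": item[0],
                        "sequence": item[1],
                        "cluster": self.assignment[item],
                    }
                )
            else:
                rows.append({"feature": item, "cluster": self.assignment[item]})
        return pd.DataFrame(rows)


def spearman_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (average ranks for ties).

    ``columns``: one column per item, one row per observation.  Constant
    columns yield NaN correlations (their rank correlation is undefined);
    the diagonal is always 1.
    """
    if columns.shape[1] < 1:
        raise ValueError("need at least one column")
    values = columns.to_numpy(dtype=float)
    n_items = values.shape[1]
    if n_items == 1:
        rho = np.ones((1, 1))
    else:
        import warnings as _warnings

        with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
            # constant columns are handled explicitly below
            _warnings.simplefilter("ignore")
            if n_items == 2:
                r = spearmanr(values[:, 0], values[:, 1]).statistic
                rho = np.array([[1.0, r], [r, 1.0]])
            else:
                rho, _ = spearmanr(values)
                rho = np.asarray(rho)
        constant = values.std(axis=0) == 0
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=columns.columns, columns=columns.columns)


def cluster_features(
    matrix: pd.DataFrame, cutoff: float = 0.9, absolute: bool = False
) -> ClusterResult:
    """Complete-linkage clustering of a correlation matrix at the cutoff.

    Items are processed in canonical (sorted) order so the result is
    invariant to input order; at equal merge heights the lexicographically
    smallest pair merges first.  Items with undefined correlations
    (constant columns) become singleton clusters, numbered after the rest.
    """
    items = sorted(matrix.index.tolist())
    if not items:
        return ClusterResult(items=[], assignment={}, n_clusters=0, cutoff=cutoff)
    rho = matrix.loc[items, items].to_numpy(dtype=float)
    if absolute:
        rho = np.abs(rho)
    # A NaN rank correlation arises only from a constant column, whose
    # whole off-diagonal row is NaN: such items become singletons.
    off_diag = ~np.eye(len(items), dtype=bool)
    defined = np.ones(len(items), dtype=bool)
    if len(items) > 1:
        for i in range(len(items)):
            defined[i] = np.any(np.isfinite(rho[i, off_diag[i]]))
    good = [i for i in range(len(items)) if defined[i]]
    bad = [i for i in range(len(items)) if not defined[i]]

    assignment: dict = {}
    link = None
    heights = None
    linkage_items = None
    next_cluster = 1
    if len(good) == 1:
        assignment[items[good[0]]] = next_cluster
        next_cluster += 1
    elif len(good) > 1:
        sub = rho[np.ix_(good, good)]
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        condensed = squareform(dist, checks=False)
        link = linkage(condensed, method="complete")
        heights = link[:, 2]
        linkage_items = [items[i] for i in good]
        # merge only pairs strictly above the cutoff: cut just below 1 - cutoff
        t = np.nextafter(1.0 - cutoff, -1.0)
        labels = fcluster(link, t=t, criterion="distance")
        # renumber clusters deterministically by first item occurrence
        remap: dict[int, int] = {}
        for idx, lab in zip(good, labels):
            if lab not in remap:
                remap[lab] = next_cluster
                next_cluster += 1
            assignment[items[idx]] = remap[lab]
    for idx in bad:
        assignment[items[idx]] = next_cluster
        next_cluster += 1
    return ClusterResult(
        items=items,
        assignment=assignment,
        n_clusters=next_cluster - 1,
        linkage_matrix=link,
        linkage_items=linkage_items,
        heights=heights,
        cutoff=cutoff,
    )


def _reference_columns(
    feature_table: pd.DataFrame, sequence: str, reading: str
) -> pd.DataFrame:
    sel = feature_table[
        (feature_table["sequence"] == sequence)
        & (feature_table["reading"] == reading)
    ]
    return sel.set_index(["patient_id", "side"]).sort_index()[list(FEATURE_NAMES)]


def cluster_sequence(
    repro: pd.DataFrame,
    feature_table: pd.DataFrame,
    sequence: str,
    cutoff: float = 0.9,
    reading: str = "L1",
    absolute: bool = False,
) -> ClusterResult:
    """Cluster the reproducible features of one sequence."""
    keep = repro[(repro["sequence"] == sequence) & repro["reproducible"]][
        "feature"
    ].tolist()
    if not keep:
        return ClusterResult(items=[], assignment={}, n_clusters=0, cutoff=cutoff)
    cols = _reference_columns(feature_table, sequence, reading)[keep]
    return cluster_features(spearman_matrix(cols), cutoff=cutoff, absolute=absolute)


def pooled_cluster(
    repro: pd.DataFrame,
    feature_table: pd.DataFrame,
    cutoff: float = 0.9,
    reading: str = "L1",
    absolute: bool = False,
) -> ClusterResult:
    """One clustering over all reproducible (feature, sequence) items.

    Observation vectors are the feature's values on its sequence across
    all ROIs of the reference reading; the result records which sequences
    co-occur within clusters.
    """
    keep = repro[repro["reproducible"]][["feature", "sequence"]]
    if keep.empty:
        return ClusterResult(items=[], assignment={}, n_clusters=0, cutoff=cutoff)
    pooled = {}
    for sequence, grp in keep.groupby("sequence"):
        cols = _reference_columns(feature_table, sequence, reading)
        for feature in grp["feature"]:
            pooled[(feature, sequence)] = cols[feature]
    pooled_df = pd.DataFrame(pooled)
    pooled_df.columns = pd.MultiIndex.from_tuples(pooled_df.columns)
    matrix = spearman_matrix(pooled_df)
    # MultiIndex columns become tuple items
    matrix.index = [tuple(t) for t in matrix.index]
    matrix.columns = [tuple(t) for t in matrix.columns]
    return cluster_features(matrix, cutoff=cutoff, absolute=absolute)


def dendrogram_newick(result: ClusterResult) -> str:
    """Newick-style nested-text export of the linkage tree, for inspection.

    Leaf names are the items (tuples joined with ``|``); branch lengths
    are merge heights ``1 - rho``.  Singleton isolates are appended as
    top-level leaves.
    """

    def leaf_name(item) -> str:
        if isinstance(item, tuple):
            return "|".join(str(x) for x in item)
        return str(item)

    if result.linkage_matrix is None:
        leaves = ",".join(leaf_name(i) for i in result.items)
        return f"({leaves});" if leaves else "();"
    link = result.linkage_matrix
    n = link.shape[0] + 1
    good_clustered = result.linkage_items

    def render(node: int, parent_height: float) -> str:
        if node < n:
            length = parent_height
            return f"{leaf_name(good_clustered[node])}:{length:.6g}"
        row = link[node - n]
        h = row[2]
        left = render(int(row[0]), h)
        right = render(int(row[1]), h)
        return f"({left},{right}):{max(parent_height - h, 0.0):.6g}"

    root_height = link[-1, 2]
    tree = render(2 * n - 2, root_height)
    isolates = [i for i in result.items if i not in set(good_clustered)]
    if isolates:
        extra = ",".join(leaf_name(i) for i in isolates)
        return f"({tree},{extra});"
    return f"{tree};"


def sequence_cooccurrence(result: ClusterResult) -> pd.DataFrame:
    """For a pooled clustering: which sequence pairs share a cluster."""
    pairs: dict[tuple[str, str], int] = {}
    for members in result.clusters().values():
        seqs = sorted({seq for _, seq in members})
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                key = (seqs[i], seqs[j])
                pairs[key] = pairs.get(key, 0) + 1
    rows = [
        {"sequence_a": a, "sequence_b": b, "shared_clusters": n}
        for (a, b), n in sorted(pairs.items())
    ]
    return pd.DataFrame(rows, columns=["sequence_a", "sequence_b", "shared_clusters"])
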