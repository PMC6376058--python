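import numpy as np
import pandas as pd
import pytest

from radiomics_repro.redundancy import (
    cluster_features,
    dendrogram_newick,
    pooled_cluster,
    sequence_cooccurrence,
    spearman_matrix,
)


def _matrix(columns: dict) -> pd.DataFrame:
    return spearman_matrix(pd.DataFrame(columns))


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self, rng):
        m = _matrix({"a": rng.normal(size=10)})
        assert m.loc["a", "a"] == 1.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        m = _matrix({"x": x, "y": np.exp(x)})
        assert m.loc["x", "y"] == pytest.approx(1.0)

    def test_hand_rank_example(self):
        m = _matrix({"x": [1.0, 2, 3, 4], "y": [1.0, 3, 2, 4]})
        assert m.loc["x", "y"] == pytest.approx(0.8)

    def test_constant_column_flagged(self, rng):
        m = _matrix({"x": rng.normal(size=8), "c": np.full(8, 2.0)})
        assert np.isnan(m.loc["x", "c"])
        assert m.loc["c", "c"] == 1.0


class TestClusterFeatures:
    def test_redundant_pair_separates_from_independent(self, rng):
        f = rng.normal(size=40)
        g = rng.normal(size=40)  # rank-independent of f
        result = cluster_features(_matrix({"f": f, "f2": 2 * f + 1, "g": g}))
        assert result.n_clusters == 2
        assert result.assignment["f"] == result.assignment["f2"]
        assert result.assignment["g"] != result.assignment["f"]

    def test_all_below_cutoff_gives_singletons(self, rng):
        cols = {f"c{i}": rng.normal(size=30) for i in range(5)}
        result = cluster_features(_matrix(cols))
        assert result.n_clusters == 5

    def test_duplicated_column_always_merges(self, rng):
        x = rng.normal(size=15)
        result = cluster_features(_matrix({"a": x, "b": x.copy()}))
        assert result.n_clusters == 1

    def test_within_cluster_pairwise_rho_exceeds_cutoff(self, rng):
        """Complete linkage makes the redundancy statement literally true."""
        n = 60
        base1 = rng.normal(size=n)
        base2 = rng.normal(size=n)
        cols = {}
        for i in range(4):
            cols[f"a{i}"] = base1 + rng.normal(size=n) * 0.05
            cols[f"b{i}"] = base2 + rng.normal(size=n) * 0.05
        m = _matrix(cols)
        result = cluster_features(m, cutoff=0.9)
        for members in result.clusters().values():
            for i, u in enumerate(members):
                for v in members[i + 1 :]:
                    assert m.loc[u, v] > 0.9

    def test_cluster_count_non_increasing_as_cutoff_decreases(self, rng):
        n = 50
        base = rng.normal(size=n)
        cols = {
            f"f{i}": base * (1 - w) + rng.normal(size=n) * w
            for i, w in enumerate(np.linspace(0, 0.8, 8))
        }
        m = _matrix(cols)
        counts = [
            cluster_features(m, cutoff=c).n_clusters
            for c in (0.95, 0.9, 0.8, 0.7, 0.5)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_item_order_invariance(self, rng):
        n = 40
        base = rng.normal(size=n)
        cols = {
            "x1": base + rng.normal(size=n) * 0.1,
            "x2": base + rng.normal(size=n) * 0.1,
            "y": rng.normal(size=n),
            "z": rng.normal(size=n),
        }
        m = _matrix(cols)
        shuffled = m.loc[["z", "x2", "y", "x1"], ["z", "x2", "y", "x1"]]
        r1 = cluster_features(m)
        r2 = cluster_features(shuffled)
        assert r1.assignment == r2.assignment

    def test_signed_correlation_does_not_merge_anticorrelated(self, rng):
        x = rng.normal(size=30)
        result = cluster_features(_matrix({"x": x, "neg": -x}))
        assert result.n_clusters == 2
        absolute = cluster_features(_matrix({"x": x, "neg": -x}), absolute=True)
        assert absolute.n_clusters == 1

    def test_constant_column_isolated_as_singleton(self, rng):
        x = rng.normal(size=20)
        result = cluster_features(_matrix({"a": x, "b": x.copy(), "c": np.full(20, 1.0)}))
        assert result.n_clusters == 2
        assert result.assignment["c"] not in (
            result.assignment["a"],
        )

    def test_empty_input_gives_empty_result(self):
        result = cluster_features(pd.DataFrame(dtype=float))
        assert result.n_clusters == 0
        assert result.items == []

    def test_newick_export_contains_all_items(self, rng):
        x = rng.normal(size=20)
        result = cluster_features(
            _matrix({"a": x, "b": x + rng.normal(size=20) * 0.01, "c": rng.normal(size=20)})
        )
        nwk = dendrogram_newick(result)
        assert nwk.endswith(";")
        for item in ("a", "b", "c"):
            assert item in nwk


def _mini_table(rng, duplicate_sequences=False):
    """A tiny two-sequence feature table restricted to a few features."""
    from radiomics_repro.features import FEATURE_NAMES

    n = 20
    rows = []
    base = {f: rng.normal(size=n) for f in FEATURE_NAMES}
    for i in range(n):
        for seq in ("T1", "ADC"):
            for reading in ("L1", "L2.1", "L2.2"):
                row = {
                    "patient_id": f"P{i:02d}",
                    "side": "left",
                    "sequence": seq,
                    "reading": reading,
                }
                for f in FEATURE_NAMES:
                    if duplicate_sequences or seq == "T1":
                        row[f] = base[f][i]
                    else:
                        row[f] = rng.normal()
                rows.append(row)
    return pd.DataFrame(rows)


class TestPooledCluster:
    def test_identical_sequences_co_cluster(self, rng):
        from radiomics_repro.features import FEATURE_NAMES

        table = _mini_table(rng, duplicate_sequences=True)
        feats = list(FEATURE_NAMES[:4])
        repro = pd.DataFrame(
            {
                "feature": feats * 2,
                "sequence": ["T1"] * 4 + ["ADC"] * 4,
                "reproducible": [True] * 8,
            }
        )
        result = pooled_cluster(repro, table)
        for f in feats:
            assert result.assignment[(f, "T1")] == result.assignment[(f, "ADC")]
        co = sequence_cooccurrence(result)
        assert co.loc[0, "shared_clusters"] >= 4

    def test_independent_sequences_never_co_cluster(self, rng):
        from radiomics_repro.features import FEATURE_NAMES

        table = _mini_table(rng, duplicate_sequences=False)
        feats = list(FEATURE_NAMES[:4])
        repro = pd.DataFrame(
            {
                "feature": feats * 2,
                "sequence": ["T1"] * 4 + ["ADC"] * 4,
                "reproducible": [True] * 8,
            }
        )
        result = pooled_cluster(repro, table)
        for members in result.clusters().values():
            seqs = {seq for _, seq in members}
            assert len(seqs) == 1

    def test_single_reproducible_item(self, rng):
        table = _mini_table(rng)
        repro = pd.DataFrame(
            {"feature": ["shape_Solidity"], "sequence": ["T1"], "reproducible": [True]}
        )
        result = pooled_cluster(repro, table)
        assert result.n_clusters == 1
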