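"""Ward variable clustering against a brute-force agglomeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from riceval import cut_tree, generate, paper_generator_spec, ward_cluster
from riceval.errors import ValidationError


def brute_force_ward(X):
    """Exhaustive Ward agglomeration over variable columns of z-scored X.

    At every step recompute the increase in within-cluster sum of squares
    for every cluster pair and merge the minimum.  Returns the partition
    sequence (frozenset of frozensets) after each merge and merge heights
    sqrt(2 * delta-SSE), the convention standard linkage tables use.
    """
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cols = {frozenset([i]): Xz[:, [i]] for i in range(X.shape[1])}
    clusters = dict(cols)
    partitions, heights = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=sorted), 2):
            na, nb = len(a), len(b)
            ma = clusters[a].mean(axis=1)
            mb = clusters[b].mean(axis=1)
            d_sse = na * nb / (na + nb) * ((ma - mb) ** 2).sum()
            if best is None or d_sse < best[0]:
                best = (d_sse, a, b)
        d_sse, a, b = best
        merged = a | b
        data = np.column_stack([clusters.pop(a), clusters.pop(b)])
        clusters[merged] = data
        partitions.append(frozenset(clusters.keys()))
        heights.append(np.sqrt(2 * d_sse))
    return partitions, heights


def tree_partitions(tree):
    """Partition after each merge, as frozensets of leaf-position sets."""
    n = len(tree.names)
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(tree.linkage):
        members[n + step] = members.pop(int(a)) | members.pop(int(b))
        out.append(frozenset(members.values()))
    return out


class TestWardOracle:
    @pytest.mark.parametrize("p,seed", [(4, 0), (5, 1), (6, 2), (6, 3)])
    def test_merge_sequence_matches_brute_force(self, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, p))
        table = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
        tree = ward_cluster(table)
        oracle_parts, oracle_heights = brute_force_ward(X)
        assert tree_partitions(tree) == oracle_parts
        assert tree.heights == pytest.approx(oracle_heights, rel=1e-9)

    def test_cut_matches_oracle_partition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 4))
        table = pd.DataFrame(X, columns=list("abcd"))
        tree = ward_cluster(table)
        oracle_parts, _ = brute_force_ward(X)
        got = cut_tree(tree, 2)
        classes = frozenset(
            frozenset(i for i, n in enumerate(table.columns) if got[n] == c)
            for c in set(got.values())
        )
        assert classes == oracle_parts[-2]  # partition before the final merge


class TestTreeProperties:
    def test_duplicated_columns_merge_first_at_zero(self, rng):
        x = rng.normal(size=20)
        t = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        tree = ward_cluster(t)
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-10)

    def test_heights_monotone(self, rng):
        t = pd.DataFrame(rng.normal(size=(30, 8)),
                         columns=[f"v{i}" for i in range(8)])
        tree = ward_cluster(t)
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_column_permutation_invariance(self, rng):
        t = pd.DataFrame(rng.normal(size=(25, 6)),
                         columns=[f"v{i}" for i in range(6)])
        p1 = cut_tree(ward_cluster(t), 3)
        shuffled = t[["v3", "v0", "v5", "v1", "v4", "v2"]]
        p2 = cut_tree(ward_cluster(shuffled), 3)
        as_sets = lambda p: {frozenset(k for k, v in p.items() if v == c)
                             for c in set(p.values())}
        assert as_sets(p1) == as_sets(p2)

    def test_zero_variance_column_named(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(ValidationError, match="flat"):
            ward_cluster(t)


class TestCut:
    def test_extreme_cuts(self, small_table):
        tree = ward_cluster(small_table)
        assert set(cut_tree(tree, 1).values()) == {1}
        singles = cut_tree(tree, 4)
        assert sorted(singles.values()) == [1, 2, 3, 4]

    def test_out_of_range(self, small_table):
        tree = ward_cluster(small_table)
        with pytest.raises(ValidationError):
            cut_tree(tree, 0)
        with pytest.raises(ValidationError):
            cut_tree(tree, 5)

    def test_texture_block_clusters_together_on_synthetic_panel(self):
        table = generate(paper_generator_spec(n_samples=2000, seed=0))
        part = cut_tree(ward_cluster(table), 5)
        texture = {"chewiness", "springiness", "adhesiveness", "hardness"}
        ids = {part[n] for n in texture}
        assert len(ids) == 1
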