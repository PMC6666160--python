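"""Ward minimum-variance clustering of quality indexes (variables).

The objects clustered are the index *columns*, each represented by its
z-scored vector of sample values, so indexes measured in different units
are comparable.  Dissimilarity is Euclidean (Ward's criterion minimizes the
increase in total within-cluster sum of squares at each merge); for
z-scored variables the squared distance is monotone in ``1 - r``, which
ties the dendrogram to the correlation structure.

The tree is a standard SciPy linkage table; cut it by class count ``k``
(the published analysis reads 5 classes off the dendrogram).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ValidationError
from .io import validate_table

__all__ = ["ClusterTree", "ward_cluster", "cut_tree"]


@dataclass(frozen=True)
class ClusterTree:
    names: tuple[str, ...]    # leaf (index) names in input order
    linkage: np.ndarray       # (n-1) x 4 SciPy merge table

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def ward_cluster(table: pd.DataFrame) -> ClusterTree:
    """Agglomerate the index columns of *table* under Ward linkage."""
    validate_table(table, min_samples=2)
    if table.shape[1] < 2:
        raise ValidationError("need at least 2 index columns to cluster")
    sd = table.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValidationError(f"zero-variance column(s): {', '.join(bad)}")
    z = (table - table.mean()) / sd          # variables as feature vectors
    Z = hierarchy.linkage(z.values.T, method="ward")
    return ClusterTree(tuple(table.columns), Z)


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Partition the leaves into *k* classes by undoing the last merges.

    Class ids are 1-based, numbered by first appearance in leaf order.
    """
    n = len(tree.names)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}]")
    raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for name, cid in zip(tree.names, raw):
        if cid not in relabel:
            relabel[cid] = len(relabel) + 1
        out[name] = relabel[cid]
    if len(relabel) != k:
        raise ValidationError(
            f"tie structure prevents a {k}-class cut (got {len(relabel)})"
        )
    return out


def partition_classes(assign: dict[str, int]) -> list[list[str]]:
    """Group an index -> class-id map into lists, ordered by class id."""
    classes: dict[int, list[str]] = {}
    for name, cid in assign.items():
        classes.setdefault(cid, []).append(name)
    return [classes[c] for c in sorted(classes)]
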