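"""Grouping of k-mer features by co-occurrence across examples.

Features that tend to appear in the same examples — the consensus word of
a binding signal together with its wildcarded and shifted variants — are
clustered so that the group lasso penalty can select or discard them as a
unit. Distance between two features is 1 minus the Spearman rank
correlation of their count columns; the agglomerative tree (average
linkage by default) is cut into exactly G clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import rankdata

from kmerlasso.kmer_features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class GroupAssignment:
    """Partition of features into groups 1..G.

    ``group_of[m]`` is the group id of feature m; ``sizes[g]`` is l_g, the
    number of features in group g.
    """

    group_of: np.ndarray
    G: int

    def __post_init__(self) -> None:
        self.group_of = np.asarray(self.group_of, dtype=np.int64)
        present = np.unique(self.group_of)
        if present.min() < 1 or present.max() > self.G:
            raise ValueError("group ids must lie in 1..G")
        if len(present) != self.G:
            raise ValueError(f"expected {self.G} nonempty groups, found {len(present)}")

    @property
    def n_features(self) -> int:
        return len(self.group_of)

    @property
    def sizes(self) -> np.ndarray:
        """l_g for g = 1..G (index 0 unused)."""
        return np.bincount(self.group_of, minlength=self.G + 1)

    def members(self, g: int) -> np.ndarray:
        return np.nonzero(self.group_of == g)[0]

    @classmethod
    def singletons(cls, p: int) -> "GroupAssignment":
        return cls(group_of=np.arange(1, p + 1), G=p)


def spearman_distance_matrix(X: np.ndarray, block: int = 4000) -> np.ndarray:
    """1 - Spearman correlation between columns of X.

    Columns with zero rank variance (constant features) are assigned
    correlation 0 with every other column. Computation is blocked over
    column chunks so DNase-scale spaces (30k features) stay within
    memory; the result equals the full-matrix computation exactly.
    """
    n, p = X.shape
    R = np.apply_along_axis(rankdata, 0, X)
    R -= R.mean(axis=0, keepdims=True)
    norms = np.sqrt((R ** 2).sum(axis=0))
    constant = norms == 0
    if constant.any():
        logger.warning("%d constant feature columns: correlation set to 0", constant.sum())
    safe = np.where(constant, 1.0, norms)
    R /= safe
    corr = np.empty((p, p))
    for i0 in range(0, p, block):
        i1 = min(i0 + block, p)
        corr[i0:i1] = R[:, i0:i1].T @ R
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return 1.0 - corr


def cluster_features(M: FeatureMatrix, G: int, linkage: str = "average") -> GroupAssignment:
    """Cut the feature dendrogram into exactly G co-occurrence groups."""
    p = M.n_features
    if not (1 <= G <= p):
        raise ValueError(f"G must be in [1, {p}], got {G}")
    if G == p:
        return GroupAssignment.singletons(p)
    X = np.asarray(M.counts.todense(), dtype=np.float64)
    D = spearman_distance_matrix(X)
    condensed = ssd.squareform(D, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    labels = sch.fcluster(Z, t=G, criterion="maxclust")
    # fcluster can return fewer clusters than requested on tied merge
    # heights; relabel to a dense 1..G' range either way
    uniq = np.unique(labels)
    remap = {old: new for new, old in enumerate(uniq, start=1)}
    dense = np.array([remap[v] for v in labels], dtype=np.int64)
    if len(uniq) != G:
        logger.warning("requested G=%d groups, dendrogram cut produced %d", G, len(uniq))
    return GroupAssignment(group_of=dense, G=len(uniq))
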