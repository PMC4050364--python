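"""Unsupervised hierarchical clustering of samples and partition scoring.

Samples are clustered on z-scored expression without reference to their
diagnostic class; a clean two-cluster cut that coincides with the known
T-ALL / pre-B-ALL labels is the sanity check that the cohort's pathological
classification is recoverable from expression alone. Defaults are
1 - Pearson correlation distance on z-scored rows with average linkage, the
classic choice for expression heatmaps; correlation distance compares the
shape of a sample's profile rather than its magnitude, which keeps a single
high-variance outlier sample from being peeled off as its own cluster.
Euclidean distance and other linkages are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, PipelineError
from .differential import pearson_outcome
from .preprocess import ZScoredMatrix
from .ranking import RankedEntry, RankedTargetList

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """Agglomeration history over samples.

    ``merges`` is the SciPy linkage matrix (n-1 rows: child ids, height,
    cluster size); leaf order is the standard dendrogram ordering.
    """

    merges: np.ndarray
    sample_ids: tuple[str, ...]
    distance: str
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.sample_ids[i] for i in order]

    def to_newick(self) -> str:
        """Newick export with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def cluster_samples(z: ZScoredMatrix | pd.DataFrame,
                    distance: str = "correlation",
                    linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of samples (columns) on z-scored rows."""
    if distance not in DISTANCES:
        raise PipelineError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise PipelineError(f"linkage must be one of {LINKAGES}")
    values = z.values if isinstance(z, ZScoredMatrix) else z
    if values.shape[1] < 2:
        raise PipelineError("clustering requires >= 2 samples")
    obs = values.to_numpy().T  # samples as observations
    if not obs.any():
        raise PipelineError("clustering on an all-zero matrix is meaningless")
    dists = pdist(obs, metric=distance)
    merges = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(
        merges=merges,
        sample_ids=tuple(values.columns),
        distance=distance,
        linkage=linkage,
    )


def cut_to_k(d: Dendrogram, k: int) -> dict[str, int]:
    """Partition into exactly k clusters by removing the k-1 highest merges.

    Returns sample id -> cluster label (1..k).
    """
    if not 1 <= k <= d.n_leaves:
        raise PipelineError(f"k must be in [1, {d.n_leaves}], got {k}")
    labels = hierarchy.fcluster(d.merges, t=k, criterion="maxclust")
    if len(set(labels)) != k:
        # exact-k fallback for tied merge heights: cut between heights
        heights = np.sort(d.heights)
        cut = heights[-(k - 1)] - 1e-12 if k > 1 else np.inf
        labels = hierarchy.fcluster(d.merges, t=cut, criterion="distance")
    return {s: int(c) for s, c in zip(d.sample_ids, labels)}


def partition_agreement(partition: dict[str, int],
                        labels: dict[str, int | str]) -> float:
    """Best-match accuracy between a clustering and known class labels.

    Maximum over one-to-one cluster<->label assignments of the fraction of
    samples correctly co-assigned; invariant to relabeling of either side.
    Solved optimally via assignment; small instances can be checked against
    exhaustive enumeration.
    """
    if set(partition) != set(labels):
        raise PipelineError("partition and labels cover different samples")
    samples = list(partition)
    clusters = sorted({partition[s] for s in samples})
    classes = sorted({labels[s] for s in samples}, key=str)
    cont = np.zeros((len(clusters), len(classes)), dtype=int)
    ci = {c: i for i, c in enumerate(clusters)}
    li = {l: j for j, l in enumerate(classes)}
    for s in samples:
        cont[ci[partition[s]], li[labels[s]]] += 1
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum()) / len(samples)


def partition_agreement_bruteforce(partition: dict[str, int],
                                   labels: dict[str, int | str]) -> float:
    """Exhaustive best-match accuracy (reference for small k)."""
    samples = list(partition)
    clusters = sorted({partition[s] for s in samples})
    classes = sorted({labels[s] for s in samples}, key=str)
    if len(clusters) > 6 or len(classes) > 6:
        raise PipelineError("exhaustive matching limited to k <= 6")
    big, small, swap = (clusters, classes, False) if len(clusters) >= len(classes) \
        else (classes, clusters, True)
    best = 0
    for perm in permutations(big, len(small)):
        mapping = dict(zip(small, perm))
        if swap:
            hits = sum(mapping.get(partition[s]) == labels[s] for s in samples)
        else:
            hits = sum(mapping.get(labels[s]) == partition[s] for s in samples)
        best = max(best, hits)
    return best / len(samples)


def select_variable_genes(values: pd.DataFrame, n: int) -> pd.DataFrame:
    """Rows with the highest variance across samples (heatmap-style gene
    selection before clustering); ties broken by row id."""
    var = values.var(axis=1, ddof=1)
    order = sorted(values.index, key=lambda p: (-var[p], p))
    return values.loc[order[:n]]


def top_discriminating_genes(m: ExpressionMatrix, labels: dict[str, int],
                             n: int) -> RankedTargetList:
    """Top-n probes by |gene-vs-outcome Pearson r|, sign retained.

    Positive r marks class-1-high probes; class-0 markers report negative r.
    """
    r = pearson_outcome(m, labels)
    df = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "symbol": m.probe_ids,
            "canonical": m.probe_ids,
            "pearson_r": r.to_numpy(),
        }
    ).dropna(subset=["pearson_r"])
    df = df.assign(_key=df["pearson_r"].abs()).sort_values(
        ["_key", "canonical", "probe_id"], ascending=[False, True, True],
        kind="mergesort",
    ).head(n)
    entries = tuple(
        RankedEntry(rank=str(i + 1), probe_id=row.probe_id, symbol=row.symbol,
                    canonical=row.canonical, score=float(row.pearson_r))
        for i, row in enumerate(df.itertuples(index=False))
    )
    return RankedTargetList(comparator="classification", metric="pearson_r",
                            entries=entries, absolute=True)
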