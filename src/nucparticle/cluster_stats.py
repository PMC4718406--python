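"""Clustering and comparison statistics for per-gene occupancy profiles.

Three pieces:

* k-means clustering (k = 9, Euclidean) of the per-gene profile matrix,
  with a stable row order (cluster label, then distance to own centroid)
  that can be re-applied to a second condition's matrix for side-by-side
  heatmap display;
* the subsampled two-condition t-test: the features are partitioned into
  n_subsets random disjoint subsets of subset_size (the same partition for
  both conditions), per-subset means are compared with a two-tailed
  unpaired Student's t-test — subsampling keeps the effective n small so
  p-values stay meaningful with thousands of genes;
* the hypergeometric gene-list overlap test against a coding-gene
  background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from nucparticle.site_profile import ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_K = 9
DEFAULT_SUBSET_SIZE = 100
DEFAULT_N_SUBSETS = 29


@dataclass
class ClusterResult:
    ids: list[str]
    labels: np.ndarray  # 1..k, aligned with ids
    centroids: np.ndarray  # k x n_bins
    row_order: list[str]  # ids sorted by cluster, then distance to own centroid
    seed: int
    n_iter: int
    inertia: float

    @property
    def assignments(self) -> dict[str, int]:
        return {fid: int(lab) for fid, lab in zip(self.ids, self.labels)}


def kmeans_profiles(
    matrix: ProfileMatrix, k: int = DEFAULT_K, seed: int = 0
) -> ClusterResult:
    """Lloyd k-means (k-means++ init, squared Euclidean) on profile rows.

    Deterministic for a given seed.  Row order is ascending cluster label,
    then ascending distance to the assigned centroid — the order used to
    lay out the heatmap and to re-order a second condition's matrix.
    """
    X = matrix.values
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("profile matrix contains non-finite values")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=300,
        random_state=seed, algorithm="lloyd",
    )
    labels0 = km.fit_predict(X)
    dists = np.linalg.norm(X - km.cluster_centers_[labels0], axis=1)
    order = np.lexsort((dists, labels0))
    return ClusterResult(
        ids=list(matrix.ids),
        labels=labels0 + 1,
        centroids=km.cluster_centers_,
        row_order=[matrix.ids[i] for i in order],
        seed=seed,
        n_iter=int(km.n_iter_),
        inertia=float(km.inertia_),
    )


def apply_cluster_order(result: ClusterResult, other: ProfileMatrix) -> ProfileMatrix:
    """Re-order another matrix's rows by the clustering's row order.

    This displays the second condition in the first condition's cluster
    layout.  All of the clustering's feature ids must be present.
    """
    index = {fid: i for i, fid in enumerate(other.ids)}
    missing = [fid for fid in result.row_order if fid not in index]
    if missing:
        raise KeyError(f"feature ids missing from matrix: {missing[:10]}")
    rows = [index[fid] for fid in result.row_order]
    return ProfileMatrix(
        ids=list(result.row_order),
        offsets=other.offsets,
        values=other.values[rows],
        truncated=[other.truncated[i] for i in rows] if other.truncated else [],
    )


def write_assignments(result: ClusterResult, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("id\tcluster\n")
        for fid, lab in zip(result.ids, result.labels):
            fh.write(f"{fid}\t{int(lab)}\n")


@dataclass
class SubsampleTTest:
    subset_size: int
    n_subsets: int
    seed: int
    means_a: np.ndarray
    means_b: np.ndarray
    t_stat: float
    p_two_tailed: float
    offset_bp: int | None = None
    degenerate: bool = False
    with_replacement: bool = False
    equal_var: bool = True
    paired: bool = False


def subsample_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    subset_size: int = DEFAULT_SUBSET_SIZE,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = 0,
    equal_var: bool = True,
    paired: bool = False,
    offset_bp: int | None = None,
) -> SubsampleTTest:
    """Two-condition comparison on random feature subsets.

    Both value vectors must be indexed by the same features.  Features are
    partitioned into ``n_subsets`` disjoint subsets of ``subset_size``
    (one shared partition, so the comparison stays per-feature-matched);
    if that needs more features than exist, subsets are drawn independently
    (overlapping across subsets, logged).  The two vectors of subset means
    are compared with a two-tailed Student's t-test (unpaired by default;
    Welch via ``equal_var=False``; paired via ``paired=True``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be 1-D and the same length")
    n = a.size
    if subset_size < 1 or n_subsets < 2:
        raise ValueError("need subset_size >= 1 and n_subsets >= 2")
    rng = np.random.default_rng(seed)
    with_replacement = subset_size * n_subsets > n
    if not with_replacement:
        perm = rng.permutation(n)[: subset_size * n_subsets]
        subsets = perm.reshape(n_subsets, subset_size)
    else:
        logger.warning(
            "subsample_ttest: %d x %d exceeds %d features; drawing overlapping subsets",
            n_subsets, subset_size, n,
        )
        replace_within = subset_size > n
        subsets = np.stack(
            [rng.choice(n, size=subset_size, replace=replace_within) for _ in range(n_subsets)]
        )
    means_a = a[subsets].mean(axis=1)
    means_b = b[subsets].mean(axis=1)

    if np.var(means_a) == 0 and np.var(means_b) == 0 and means_a.mean() == means_b.mean():
        return SubsampleTTest(
            subset_size=subset_size, n_subsets=n_subsets, seed=seed,
            means_a=means_a, means_b=means_b, t_stat=0.0, p_two_tailed=1.0,
            offset_bp=offset_bp, degenerate=True,
            with_replacement=with_replacement, equal_var=equal_var, paired=paired,
        )
    if paired:
        t_stat, p = stats.ttest_rel(means_a, means_b)
    else:
        t_stat, p = stats.ttest_ind(means_a, means_b, equal_var=equal_var)
    return SubsampleTTest(
        subset_size=subset_size, n_subsets=n_subsets, seed=seed,
        means_a=means_a, means_b=means_b,
        t_stat=float(t_stat), p_two_tailed=float(p),
        offset_bp=offset_bp, with_replacement=with_replacement,
        equal_var=equal_var, paired=paired,
    )


@dataclass
class OverlapTest:
    n_background: int
    n_a: int
    n_b: int
    n_overlap: int
    p_hyper: float


def overlap_test(
    list_a: Sequence[str], list_b: Sequence[str], background_size: int
) -> OverlapTest:
    """Upper-tail hypergeometric test for the overlap of two gene lists.

    ``p = P(X >= n_overlap)`` where X counts the overlap of two random
    lists of the observed sizes drawn from ``background_size`` coding
    genes.
    """
    set_a, set_b = set(list_a), set(list_b)
    n_a, n_b = len(set_a), len(set_b)
    n_overlap = len(set_a & set_b)
    if max(n_a, n_b) > background_size:
        raise ValueError("list larger than background population")
    if n_overlap > min(n_a, n_b):  # unreachable for real sets; guards manual counts
        raise ValueError("overlap exceeds smaller list size")
    p = float(stats.hypergeom.sf(n_overlap - 1, background_size, n_a, n_b))
    return OverlapTest(
        n_background=background_size, n_a=n_a, n_b=n_b,
        n_overlap=n_overlap, p_hyper=min(p, 1.0),
    )
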