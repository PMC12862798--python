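"""Correlation-based clustering of contact distances.

The contact-distance correlation matrix is partitioned into contact
clusters with Leiden community detection under the constant Potts model
(CPM).  The CPM objective of a partition is

    sum_c [ W_c - gamma * n_c (n_c - 1) / 2 ]

where W_c is the summed intra-cluster similarity (each unordered pair
counted once, diagonal excluded), n_c the cluster size, and gamma the
resolution parameter in (0, 1]: large gamma yields many small, highly
correlated clusters, small gamma few large, loosely correlated ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

import igraph as ig
import leidenalg

from .contacts import DistanceSeries, subsample

__all__ = [
    "CorrelationModel",
    "MosaicConfig",
    "ClusterPartition",
    "stack_series",
    "correlation_matrix",
    "cpm_objective",
    "leiden_cpm",
    "reorder_block_diagonal",
    "gamma_scan",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationModel:
    """Feature-by-feature similarity matrix in [0, 1].

    ``matrix`` holds the similarity used for clustering (absolute Pearson
    correlation or normalized mutual information); for the Pearson method
    the signed correlation matrix is retained in ``signed`` for reporting.
    """

    features: list[str]
    matrix: np.ndarray
    method: str = "pearson_abs"
    signed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.features)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match feature count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("correlation matrix contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("correlation matrix must be symmetric")
        if self.matrix.min() < -1e-12 or self.matrix.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class MosaicConfig:
    """Clustering configuration.

    gamma : CPM resolution in (0, 1].
    min_cluster_size : clusters smaller than this are reported as noise.
    n_restarts : seeded Leiden restarts; best CPM objective wins.
    """

    gamma: float = 0.5
    min_cluster_size: int = 2
    n_restarts: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class ClusterPartition:
    """A partition of features into contact clusters plus noise.

    Clusters are ordered by descending size, ties broken by the smallest
    contained feature index; features in clusters below min_cluster_size are
    collected under ``noise``.  ``objective`` is the CPM score of the full
    partition (noise features as their original communities).
    """

    clusters: list[list[int]]
    noise: list[int]
    objective: float
    gamma: float
    features: list[str] = field(default_factory=list)

    @property
    def assignment(self) -> dict[int, int]:
        """feature index -> cluster id (noise features map to -1)."""
        out = {j: -1 for j in self.noise}
        for cid, members in enumerate(self.clusters):
            for j in members:
                out[j] = cid
        return out

    @property
    def labels(self) -> np.ndarray:
        n = len(self.noise) + sum(len(c) for c in self.clusters)
        lab = np.full(n, -1, dtype=int)
        for cid, members in enumerate(self.clusters):
            lab[members] = cid
        return lab

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# correlation matrix


def stack_series(
    series: Sequence[DistanceSeries],
    stride: int = 5,
    center_per_trajectory: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Concatenate per-trajectory series into a features-by-frames matrix.

    Series are grouped by contact name, subsampled by ``stride``, centered
    per trajectory (so between-run offsets do not masquerade as
    correlation), and concatenated across trajectories in a deterministic
    order.  All features must be observed in the same trajectories with
    equal lengths.
    """
    by_feature: dict[str, dict[str, np.ndarray]] = {}
    for s in series:
        sub = subsample(s, stride) if stride > 1 else s
        by_feature.setdefault(s.name, {})[s.trajectory_id] = sub.values
    names = sorted(by_feature, key=_feature_sort_key)
    traj_ids = sorted(by_feature[names[0]])
    rows = []
    for name in names:
        chunks = []
        if sorted(by_feature[name]) != traj_ids:
            raise ValueError(f"feature {name} missing in some trajectories")
        for tid in traj_ids:
            v = by_feature[name][tid]
            chunks.append(v - v.mean() if center_per_trajectory else v)
        rows.append(np.concatenate(chunks))
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("features have unequal total series lengths")
    return names, np.vstack(rows)


def _feature_sort_key(name: str):
    try:
        a, b = name.split("_")
        return (0, int(a), int(b))
    except ValueError:
        return (1, name, "")


def _nmi_matrix(X: np.ndarray) -> np.ndarray:
    """Normalized mutual information with sqrt(N) equal-width bins.

    MI is estimated from a 2-D histogram with ceil(sqrt(n_frames)) bins per
    variable and normalized by the arithmetic mean of the marginal
    entropies; the diagonal is 1 by construction.
    """
    n_feat, n_frames = X.shape
    n_bins = int(np.ceil(np.sqrt(n_frames)))
    digitized = np.empty_like(X, dtype=int)
    entropies = np.empty(n_feat)
    for j in range(n_feat):
        lo, hi = X[j].min(), X[j].max()
        if hi <= lo:  # zero variance
            digitized[j] = 0
            entropies[j] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        digitized[j] = np.clip(np.searchsorted(edges, X[j], side="right") - 1, 0, n_bins - 1)
        p = np.bincount(digitized[j], minlength=n_bins) / n_frames
        p = p[p > 0]
        entropies[j] = -(p * np.log(p)).sum()
    M = np.eye(n_feat)
    for j in range(n_feat):
        for k in range(j + 1, n_feat):
            denom = 0.5 * (entropies[j] + entropies[k])
            if denom <= 0:
                M[j, k] = M[k, j] = 0.0
                continue
            joint = np.bincount(
                digitized[j] * n_bins + digitized[k], minlength=n_bins * n_bins
            ).reshape(n_bins, n_bins) / n_frames
            pj = joint.sum(axis=1)
            pk = joint.sum(axis=0)
            nz = joint > 0
            mi = (joint[nz] * np.log(joint[nz] / np.outer(pj, pk)[nz])).sum()
            M[j, k] = M[k, j] = min(max(mi / denom, 0.0), 1.0)
    return M


def correlation_matrix(
    X: np.ndarray | tuple[list[str], np.ndarray],
    method: str = "pearson_abs",
    features: list[str] | None = None,
) -> CorrelationModel:
    """Similarity matrix between contact-distance series.

    ``pearson_abs`` uses |Pearson r| -- anticorrelated contacts are just as
    dynamically coupled as correlated ones; ``nmi`` uses histogram-based
    normalized mutual information for strongly nonlinear coupling.
    Zero-variance features get zero off-diagonal similarity with a warning.
    """
    if isinstance(X, tuple):
        features, X = X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two features")
    if features is None:
        features = [f"f{j}" for j in range(X.shape[0])]

    flat = np.flatnonzero(X.std(axis=1) == 0)
    if flat.size:
        logger.warning(
            "zero-variance features %s: off-diagonal similarity set to 0",
            [features[j] for j in flat],
        )

    if method == "pearson_abs":
        with np.errstate(invalid="ignore", divide="ignore"):
            signed = np.corrcoef(X)
        signed[~np.isfinite(signed)] = 0.0
        np.fill_diagonal(signed, 1.0)
        signed = np.clip(signed, -1.0, 1.0)
        matrix = np.abs(signed)
        for j in flat:
            matrix[j, :] = matrix[:, j] = 0.0
            matrix[j, j] = 1.0
        return CorrelationModel(list(features), matrix, method, signed=signed)
    if method == "nmi":
        matrix = _nmi_matrix(X)
        for j in flat:
            matrix[j, :] = matrix[:, j] = 0.0
            matrix[j, j] = 1.0
        return CorrelationModel(list(features), matrix, method)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Leiden / CPM


def cpm_objective(matrix: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """CPM score: intra-cluster similarity minus gamma per intra pair."""
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    score = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        n = members.size
        block = matrix[np.ix_(members, members)]
        w = (block.sum() - np.trace(block)) / 2.0
        score += w - gamma * n * (n - 1) / 2.0
    return float(score)


def _membership_tiebreak(labels: np.ndarray) -> tuple:
    """Canonical form for tie-breaking: fewer clusters, then lexicographic."""
    relabel: dict[int, int] = {}
    canon = []
    for l in labels:
        if l not in relabel:
            relabel[l] = len(relabel)
        canon.append(relabel[l])
    return (len(relabel), tuple(canon))


def leiden_cpm(model: CorrelationModel, config: MosaicConfig | None = None) -> ClusterPartition:
    """Partition features by Leiden community detection under CPM.

    Runs ``n_restarts`` seeded Leiden optimizations on the fully connected
    similarity graph and keeps the best CPM objective (ties: fewer clusters,
    then lexicographically smallest membership).  Communities smaller than
    ``min_cluster_size`` are reported as noise; the objective refers to the
    raw winning partition.
    """
    config = config or MosaicConfig()
    n = model.n_features
    W = model.matrix
    iu = np.triu_indices(n, k=1)
    edges = list(zip(iu[0].tolist(), iu[1].tolist()))
    weights = W[iu].tolist()
    g = ig.Graph(n=n, edges=edges)

    best: tuple | None = None
    for r in range(config.n_restarts):
        part = leidenalg.find_partition(
            g,
            leidenalg.CPMVertexPartition,
            weights=weights,
            resolution_parameter=config.gamma,
            seed=config.seed + r,
            n_iterations=-1,
        )
        labels = np.asarray(part.membership)
        obj = cpm_objective(W, labels, config.gamma)
        key = (-obj, *_membership_tiebreak(labels))
        if best is None or key < best[0]:
            best = (key, labels, obj)
    assert best is not None
    labels, objective = best[1], best[2]

    groups: dict[int, list[int]] = {}
    for j, l in enumerate(labels):
        groups.setdefault(int(l), []).append(j)
    clusters = [sorted(m) for m in groups.values() if len(m) >= config.min_cluster_size]
    noise = sorted(j for m in groups.values() if len(m) < config.min_cluster_size for j in m)
    clusters.sort(key=lambda m: (-len(m), m[0]))
    return ClusterPartition(
        clusters=clusters,
        noise=noise,
        objective=objective,
        gamma=config.gamma,
        features=list(model.features),
    )


def reorder_block_diagonal(
    model: CorrelationModel, partition: ClusterPartition
) -> tuple[CorrelationModel, np.ndarray]:
    """Permute the matrix so clusters form contiguous diagonal blocks.

    Returns the permuted model and the permutation applied (new order of
    original feature indices: clusters in partition order, noise last).
    Entries are unchanged, only rearranged.
    """
    n = model.n_features
    perm = [j for members in partition.clusters for j in members] + list(partition.noise)
    if sorted(perm) != list(range(n)):
        raise ValueError("partition does not cover the model's feature set")
    perm = np.asarray(perm)
    reordered = CorrelationModel(
        features=[model.features[j] for j in perm],
        matrix=model.matrix[np.ix_(perm, perm)],
        method=model.method,
        signed=None if model.signed is None else model.signed[np.ix_(perm, perm)],
    )
    return reordered, perm


def mean_intra_cluster_correlation(
    model: CorrelationModel, partition: ClusterPartition
) -> float:
    """Mean similarity over intra-cluster pairs (nan if no such pair)."""
    vals = []
    for members in partition.clusters:
        m = np.asarray(members)
        if m.size < 2:
            continue
        block = model.matrix[np.ix_(m, m)]
        iu = np.triu_indices(m.size, k=1)
        vals.append(block[iu])
    if not vals:
        return float("nan")
    return float(np.concatenate(vals).mean())


def gamma_scan(
    model: CorrelationModel,
    gammas: Sequence[float],
    config: MosaicConfig | None = None,
) -> list[dict]:
    """Cluster at each resolution gamma with a shared seed policy.

    Returns one record per gamma with the partition, cluster count and mean
    intra-cluster similarity -- the standard diagnostic for choosing gamma.
    """
    config = config or MosaicConfig()
    if len(gammas) == 0:
        raise ValueError("gammas must be nonempty")
    out = []
    for gamma in gammas:
        cfg = MosaicConfig(
            gamma=float(gamma),
            min_cluster_size=config.min_cluster_size,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        part = leiden_cpm(model, cfg)
        out.append(
            {
                "gamma": float(gamma),
                "partition": part,
                "n_clusters": part.n_clusters,
                "mean_intra_correlation": mean_intra_cluster_correlation(model, part),
            }
        )
    return out
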