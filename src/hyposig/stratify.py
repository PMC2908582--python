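"""Patient stratification on signature expression and its stability.

``kmeans2`` is Lloyd's algorithm with k = 2, euclidean distance and a
configurable number of random restarts (best within-cluster sum of
squares wins), seeded for reproducibility.  The cluster whose mean
signature expression is higher is labeled "poor" prognosis.

The permutation stability test re-clusters the cohort on randomly drawn
probeset sets of the same size as the signature and measures the
misclassification distance (minimal disagreement over cluster-label
permutations, in [0, 0.5] for k = 2) to the reference clustering.  Each
permutation distance is compared with its exact chance expectation — the
hypergeometric expectation of the distance between two independent
labelings with the realized cluster sizes — and a one-sample t-test of
(distance - expectation) against 0 summarizes whether the random
clusterings track the reference more (or less) than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .io import ExpressionMatrix
from .signature import Signature

__all__ = [
    "ClusterAssignment",
    "StabilityResult",
    "kmeans2",
    "label_prognosis",
    "misclassification_distance",
    "expected_chance_distance",
    "permutation_stability",
    "hcluster_complete",
]


@dataclass
class ClusterAssignment:
    """sample -> cluster in {1, 2}, with fit quality and prognosis labels."""

    sample_ids: list[str]
    labels: np.ndarray  # values in {1, 2}
    inertia: float  # within-cluster sum of squares
    prognosis: dict[int, str] | None = None  # cluster -> "poor"/"good"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("label/sample length mismatch")
        if not set(np.unique(self.labels)) <= {1, 2}:
            raise ValueError("labels must be in {1, 2}")
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")

    @property
    def sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in (1, 2)}

    def samples_in(self, cluster: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == cluster]

    def poor_samples(self) -> list[str]:
        if self.prognosis is None:
            raise ValueError("prognosis labels not assigned")
        poor = [c for c, lab in self.prognosis.items() if lab == "poor"][0]
        return self.samples_in(poor)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


@dataclass
class StabilityResult:
    distances: np.ndarray
    baselines: np.ndarray
    t_statistic: float
    p_value: float
    n_perm: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.distances) != self.n_perm:
            raise ValueError("distance vector length != n_perm")
        if ((self.distances < 0) | (self.distances > 0.5 + 1e-12)).any():
            raise ValueError("distances must be in [0, 0.5]")


def _lloyd(M: np.ndarray, centers: np.ndarray, max_steps: int = 100, trace: list | None = None):
    """One Lloyd run to convergence; WCSS never increases across steps."""
    labels = np.zeros(M.shape[0], dtype=int)
    for step in range(max_steps):
        d = ((M[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        for c in range(2):
            if not (new_labels == c).any():  # re-seed empty cluster at the worst-fit point
                far = d[np.arange(len(new_labels)), new_labels].argmax()
                new_labels[far] = c
        if (new_labels == labels).all() and step != 0:
            break
        labels = new_labels
        centers = np.vstack([M[labels == c].mean(axis=0) for c in range(2)])
        if trace is not None:
            trace.append(float(((M - centers[labels]) ** 2).sum()))
    inertia = float(((M - centers[labels]) ** 2).sum())
    return labels, inertia


def kmeans2(
    M: np.ndarray | pd.DataFrame,
    restarts: int = 100,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> ClusterAssignment:
    """k = 2 Lloyd clustering, best of ``restarts`` random initializations.

    Rows are samples.  Each restart initializes the two centroids at a
    random pair of distinct data points and runs Lloyd's iteration to
    convergence; the restart with the smallest within-cluster sum of
    squares wins.  Deterministic under ``seed``.
    """
    if isinstance(M, pd.DataFrame):
        sample_ids = sample_ids or list(M.index)
        M = M.to_numpy(dtype=float)
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(M, axis=0).max() == 0:
        raise ValueError("all points identical: clustering is degenerate")
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(restarts):
        i, j = rng.choice(n, size=2, replace=False)
        if (M[i] == M[j]).all():
            continue
        labels, inertia = _lloyd(M, M[[i, j]].copy())
        if inertia < best_inertia - 1e-12:
            best_inertia, best_labels = inertia, labels
    if best_labels is None:
        raise ValueError("could not find two distinct initial points")
    return ClusterAssignment(sample_ids, best_labels + 1, best_inertia)


def label_prognosis(A: ClusterAssignment, M_sig: np.ndarray | pd.DataFrame) -> ClusterAssignment:
    """Label the higher-expression cluster "poor", the other "good".

    ``M_sig`` is the samples x signature-probesets matrix the clustering
    was computed on (same row order as ``A.sample_ids``).
    """
    if isinstance(M_sig, pd.DataFrame):
        M_sig = M_sig.to_numpy(dtype=float)
    means = {c: float(M_sig[A.labels == c].mean()) for c in (1, 2)}
    if means[1] == means[2]:
        raise ValueError("exact tie in cluster mean expression; change the seed")
    poor = 1 if means[1] > means[2] else 2
    A.prognosis = {poor: "poor", 3 - poor: "good"}
    return A


def misclassification_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal disagreement fraction over cluster-label permutations (k=2)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same samples")
    mism = float(np.mean(a != b))
    return min(mism, 1.0 - mism)


def expected_chance_distance(n: int, m_a: int, m_b: int) -> float:
    """Exact E[misclassification distance] for independent 2-labelings.

    One labeling has m_a samples in cluster 1, the other m_b; the overlap
    K between the two cluster-1 sets is Hypergeom(n, m_a, m_b), and the
    distance is min(u, 1-u) with u = (m_a + m_b - 2K)/n.
    """
    k = np.arange(max(0, m_a + m_b - n), min(m_a, m_b) + 1)
    pmf = stats.hypergeom.pmf(k, n, m_a, m_b)
    u = (m_a + m_b - 2 * k) / n
    return float(np.sum(pmf * np.minimum(u, 1.0 - u)))


def permutation_stability(
    E_tumors: ExpressionMatrix,
    S: Signature,
    n_perm: int = 300,
    seed: int = 0,
    restarts: int = 100,
    zscore: bool = True,
) -> StabilityResult:
    """Random-signature permutation test of clustering stability.

    The reference labeling is ``kmeans2`` on the signature probesets.
    Each permutation draws |S| probesets uniformly without replacement
    from the full matrix, re-clusters, and records the misclassification
    distance to the reference.  The t-test compares the distances with
    their exact per-permutation chance expectations: a significantly
    smaller mean distance means random probeset sets reproduce the
    reference split better than chance (the cohort structure is
    pervasive), a larger mean means the signature split is not recovered.
    Pure function of (matrix, signature, n_perm, seed).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if len(S) > E_tumors.shape[0]:
        raise ValueError("signature larger than the probeset pool")
    rng = np.random.default_rng(seed)
    M = prepare_cluster_matrix(E_tumors, zscore=zscore)
    sig_idx = [E_tumors.probeset_ids.index(p) for p in S.probesets]
    n = M.shape[0]
    ref = kmeans2(M[:, sig_idx], restarts=restarts, seed=int(rng.integers(2**31)))
    m_ref = int((ref.labels == 1).sum())
    distances = np.empty(n_perm)
    baselines = np.empty(n_perm)
    p_total = E_tumors.shape[0]
    for i in range(n_perm):
        draw = rng.choice(p_total, size=len(S), replace=False)
        perm = kmeans2(M[:, draw], restarts=restarts, seed=int(rng.integers(2**31)))
        distances[i] = misclassification_distance(ref.labels, perm.labels)
        baselines[i] = expected_chance_distance(n, m_ref, int((perm.labels == 1).sum()))
    t, p = stats.ttest_1samp(distances - baselines, 0.0)
    return StabilityResult(distances, baselines, float(t), float(p), n_perm)


def prepare_cluster_matrix(E: ExpressionMatrix, zscore: bool = True) -> np.ndarray:
    """Samples x probesets matrix for clustering.

    Linear input is log2-transformed; per-probeset z-scoring (the
    heatmap-style scaling) is on by default.  Constant probesets map
    to 0 under z-scoring.
    """
    V = E.values
    if E.scale == "linear":
        V = np.log2(V)
    M = V.T  # samples x probesets
    if zscore:
        mean = M.mean(axis=0)
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        M = (M - mean) / sd
    return M


def hcluster_complete(rows: np.ndarray | pd.DataFrame):
    """Complete-linkage hierarchical clustering on euclidean distances.

    Returns (leaf order, merge tree in scipy linkage format); the leaf
    order is the heatmap row order.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_numpy(dtype=float)
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    Z = linkage(rows, method="complete", metric="euclidean")
    return leaves_list(Z), Z
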