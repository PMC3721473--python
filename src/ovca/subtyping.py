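"""Subtype discovery by resampled consensus clustering with validation metrics.

The consensus matrix records, per sample pair, the fraction of subsampled
clustering runs in which the pair co-clustered among the runs where both
were drawn. Final labels come from average-linkage clustering of 1 - M.
Validation: per-sample silhouette widths (core = SW > 0), a Gaussian-null
cluster-significance test, and label concordance/ARI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, cut_tree
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from ovca.io_formats import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "SubtypeAssignment",
    "hierarchical_average_linkage",
    "consensus_cluster",
    "select_k",
    "silhouette_widths",
    "sigclust_test",
    "concordance",
    "make_assignment",
]


@dataclass
class ConsensusResult:
    """Consensus clustering output at one value of k."""

    k: int
    consensus: np.ndarray  # samples x samples, in [0, 1]
    co_sampled: np.ndarray  # pair co-sampling counts
    labels: np.ndarray  # 1..k
    linkage: np.ndarray  # scipy linkage over 1 - consensus

    def __post_init__(self) -> None:
        M = self.consensus
        if not np.allclose(M, M.T):
            raise ValueError("consensus matrix must be symmetric")
        if np.any(M < -1e-12) or np.any(M > 1 + 1e-12):
            raise ValueError("consensus entries must lie in [0, 1]")


@dataclass
class SubtypeAssignment:
    """Per-sample subtype label, silhouette width and core flag (SW > 0)."""

    sample_ids: list[str]
    labels: np.ndarray
    silhouette: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.silhouette = np.asarray(self.silhouette, dtype=float)
        if not (len(self.sample_ids) == len(self.labels) == len(self.silhouette)):
            raise ValueError("assignment columns have unequal lengths")

    @property
    def core(self) -> np.ndarray:
        return self.silhouette > 0


def hierarchical_average_linkage(distance: np.ndarray):
    """UPGMA merge tree over a symmetric distance matrix; returns the linkage.

    Use :func:`cut_to_k` to extract flat labels.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(D)):
        raise ValueError("NaN in distance matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    return average(squareform(D, checks=False))


def cut_to_k(linkage: np.ndarray, k: int) -> np.ndarray:
    """Flat 1-based cluster labels from a linkage tree cut to k clusters."""
    return cut_tree(linkage, n_clusters=k).ravel() + 1


def consensus_cluster(
    expr: ExpressionMatrix,
    k_values,
    n_iter: int = 1000,
    subsample: float = 0.8,
    distance: str = "euclidean",
    seed: int = 0,
) -> dict[int, ConsensusResult]:
    """Resampled-consensus clustering of samples over a grid of k.

    Each iteration draws ``subsample`` of the samples without replacement
    (genes are never resampled), clusters them by average linkage and cuts
    to k. The consensus matrix divides co-clustering counts by co-sampling
    counts; never-co-sampled pairs are imputed 0 with a warning.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    k_values = sorted(set(int(k) for k in k_values))
    n = expr.n_samples
    if distance == "euclidean":
        values = expr.values
    elif distance == "pearson":
        values = expr.values
    else:
        raise ValueError(f"unsupported distance {distance!r}")

    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))
    draws = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(n_iter)]

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_values}
    for idx in draws:
        sub = values[:, idx]
        if distance == "euclidean":
            D = squareform(pdist(sub.T, metric="euclidean"))
        else:
            D = 1.0 - np.corrcoef(sub.T)
            np.fill_diagonal(D, 0.0)
            D = np.maximum(D, 0.0)
        Z = hierarchical_average_linkage(D)
        co_sampled[np.ix_(idx, idx)] += 1
        for k in k_values:
            labs = cut_to_k(Z, min(k, len(idx)))
            same = labs[:, None] == labs[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same

    results: dict[int, ConsensusResult] = {}
    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} sample pair(s) never co-sampled; consensus imputed 0",
            stacklevel=2,
        )
    denom = np.where(co_sampled == 0, 1.0, co_sampled)
    for k in k_values:
        M = co_clustered[k] / denom
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        Z = hierarchical_average_linkage(1.0 - M)
        labels = cut_to_k(Z, k)
        results[k] = ConsensusResult(k, M, co_sampled, labels, Z)
    return results


def select_k(results: dict[int, ConsensusResult], pac_bounds=(0.1, 0.9)):
    """Per-k consensus-distribution metrics and an advisory recommended k.

    Returns (metrics dict per k, recommended k). Metrics: area under the
    consensus CDF, delta-area relative to the previous k, PAC (fraction of
    off-diagonal consensus entries inside ``pac_bounds``), and mean
    within-cluster consensus ("purity" substitute).
    """
    if len(results) < 2:
        raise ValueError("select_k needs results for >= 2 values of k")
    lo, hi = pac_bounds
    ks = sorted(results)
    metrics: dict[int, dict[str, float]] = {}
    prev_auc = None
    for k in ks:
        res = results[k]
        n = res.consensus.shape[0]
        iu = np.triu_indices(n, 1)
        vals = np.sort(res.consensus[iu])
        # area under the empirical CDF of consensus entries on [0, 1]
        grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(vals, grid, side="right") / len(vals)
        auc = float(np.trapezoid(cdf, grid))
        pac = float(np.mean((vals > lo) & (vals < hi)))
        within = []
        for c in np.unique(res.labels):
            members = np.where(res.labels == c)[0]
            if len(members) < 2:
                continue
            sub = res.consensus[np.ix_(members, members)]
            within.append(sub[np.triu_indices(len(members), 1)].mean())
        purity = float(np.mean(within)) if within else float("nan")
        delta = float("nan") if prev_auc is None else (auc - prev_auc) / max(prev_auc, 1e-12)
        metrics[k] = {"auc_cdf": auc, "delta_area": delta, "pac": pac, "purity": purity}
        prev_auc = auc
    # elbow: the largest k whose delta-area still exceeds 2.5% relative gain
    recommended = ks[0]
    for k in ks[1:]:
        if metrics[k]["delta_area"] > 0.025:
            recommended = k
    return metrics, recommended


def silhouette_widths(distance: np.ndarray, labels) -> np.ndarray:
    """Per-sample silhouette width SW(i) = (b - a) / max(a, b).

    a = mean distance to own cluster (excluding self); b = smallest mean
    distance to another cluster. Singleton-cluster samples get SW = 0 with a
    warning.
    """
    D = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    n = len(labels)
    sw = np.zeros(n)
    sizes = {c: int((labels == c).sum()) for c in classes}
    if any(s == 1 for s in sizes.values()):
        warnings.warn("singleton cluster(s): silhouette width set to 0", stacklevel=2)
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            sw[i] = 0.0
            continue
        mask_own = labels == own
        a = D[i, mask_own].sum() / (sizes[own] - 1)
        b = min(D[i, labels == c].mean() for c in classes if c != own)
        denom = max(a, b)
        sw[i] = 0.0 if denom == 0 else (b - a) / denom
    return sw


def make_assignment(
    expr: ExpressionMatrix, labels, min_cluster_frac: float = 0.02, other_label: str = "Other"
) -> SubtypeAssignment:
    """Package labels with silhouette widths; relabel tiny clusters as Other."""
    labels = np.asarray(labels, dtype=object).copy()
    n = len(labels)
    for c, count in zip(*np.unique(labels, return_counts=True)):
        if count < max(2, min_cluster_frac * n):
            labels[labels == c] = other_label
    D = squareform(pdist(expr.values.T, metric="euclidean"))
    sw = silhouette_widths(D, labels)
    return SubtypeAssignment(list(expr.sample_ids), labels, sw)


def _two_means_ci(X: np.ndarray, n_init: int, rng: np.random.Generator) -> float:
    """Cluster index of the best 2-means split: within-SS / total-SS."""
    n = X.shape[0]
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0:
        return 1.0
    # deterministic init from the extreme principal projection + random inits
    centered = X - X.mean(axis=0)
    u = centered @ centered[np.argmax((centered**2).sum(axis=1))]
    inits = [u > np.median(u)]
    for _ in range(n_init):
        lab = np.zeros(n, dtype=bool)
        lab[rng.choice(n, size=n // 2, replace=False)] = True
        inits.append(lab)
    best = np.inf
    for lab in inits:
        lab = lab.copy()
        if lab.all() or not lab.any():
            continue
        for _ in range(100):
            c1 = X[lab].mean(axis=0)
            c0 = X[~lab].mean(axis=0)
            d1 = ((X - c1) ** 2).sum(axis=1)
            d0 = ((X - c0) ** 2).sum(axis=1)
            new = d1 < d0
            if new.all() or not new.any():
                break
            if np.array_equal(new, lab):
                break
            lab = new
        wss = float(d1[lab].sum() + d0[~lab].sum())
        best = min(best, wss)
    return best / total


def sigclust_test(
    expr: ExpressionMatrix | np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    n_init: int = 3,
) -> tuple[float, float]:
    """Two-cluster significance against a single-Gaussian null.

    The statistic is the cluster index (within-cluster SS over total SS) of
    the best 2-means split. The null simulates a mean-zero Gaussian with
    diagonal covariance equal to the data's covariance eigenvalues floored at
    a MAD-based background-noise variance. Returns ``(p_value, observed_ci)``
    with p = fraction of null CIs <= observed.
    """
    X = expr.values.T if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=float)
    n, d = X.shape
    if n < 4:
        raise ValueError("sigclust needs >= 4 samples")
    rng = np.random.default_rng(seed)
    ci_obs = _two_means_ci(X, n_init, rng)

    centered = X - X.mean(axis=0)
    mad = np.median(np.abs(centered - np.median(centered)))
    sigma2_noise = (mad / 0.6744897501960817) ** 2
    # eigenvalues of the sample covariance via SVD (rank <= min(n-1, d))
    svals = np.linalg.svd(centered, compute_uv=False)
    raw = np.zeros(d)
    raw[: len(svals)] = svals**2 / max(n - 1, 1)
    # soft method: shift large eigenvalues down by tau (floored at the
    # background-noise variance) so the total variance is preserved; the
    # hard floor alone inflates anisotropy and makes the test conservative
    total = raw.sum()

    def _soft(tau):
        return np.maximum(raw - tau, sigma2_noise)

    if _soft(0.0).sum() <= total:
        eig = _soft(0.0)
    else:
        lo_t, hi_t = 0.0, float(raw.max())
        for _ in range(100):
            mid = 0.5 * (lo_t + hi_t)
            if _soft(mid).sum() > total:
                lo_t = mid
            else:
                hi_t = mid
        eig = _soft(hi_t)

    null_ci = np.empty(n_sim)
    scale = np.sqrt(eig)
    for s in range(n_sim):
        sim = rng.normal(size=(n, d)) * scale
        null_ci[s] = _two_means_ci(sim, n_init, rng)
    p = float(np.mean(null_ci <= ci_obs))
    return p, ci_obs


def concordance(labels_a, labels_b, mapping: str = "bestmatch"):
    """Percent agreement between two labelings plus the adjusted Rand index.

    ``bestmatch`` finds the optimal one-to-one label correspondence by
    Hungarian assignment before counting agreements; ``given`` compares the
    label strings directly.
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("labelings must cover the same non-empty sample set")
    ari = float(adjusted_rand_score(a.astype(str), b.astype(str)))
    if mapping == "given":
        agree = float(np.mean(a == b)) * 100.0
        return agree, ari
    if mapping != "bestmatch":
        raise ValueError(f"unknown mapping {mapping!r}")
    la, lb = np.unique(a), np.unique(b)
    C = np.zeros((len(la), len(lb)))
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            C[i, j] = np.sum((a == x) & (b == y))
    rows, cols = linear_sum_assignment(-C)
    agree = float(C[rows, cols].sum()) / len(a) * 100.0
    return agree, ari
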