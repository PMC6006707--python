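"""Statistical analysis of model ensembles.

The ensemble's stable states (log2 levels, pooled over models) are
z-scored per gene, clustered by average-linkage agglomeration on
Euclidean distances, and projected onto principal components; "gene
states" are the major clusters whose fraction of all states exceeds a
cutoff (5% by default).

Convergence of ensemble statistics is diagnosed by the mean pairwise
Bhattacharyya distance

    D_B(p, q) = -ln( sum_x sqrt(p(x) q(x)) )

between replicate runs at a given setting (nRM or nIC) and replicates at
the largest setting, applied to the per-model state-count distribution
("dissimilarity of states") and to per-gene histograms of expression
levels ("dissimilarity of expressions").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import false_discovery_control, mannwhitneyu
from sklearn.decomposition import PCA

__all__ = [
    "normalize_expressions",
    "apply_normalization",
    "zero_expression_z",
    "ClusterReport",
    "hierarchical_clusters",
    "PCAResult",
    "pca_project",
    "project_onto",
    "state_count_distribution",
    "bhattacharyya",
    "kl_divergence",
    "replicate_dissimilarity",
    "expression_histogram",
    "histogram_support",
    "minimal_setting_scan",
    "ParameterDifferentiation",
    "parameter_differentiation",
]

#: Cap used for infinite dissimilarities (distributions with disjoint
#: support); roughly -ln of the smallest positive double.
DISSIMILARITY_CAP = 700.0


# ---------------------------------------------------------------------------
# normalization

def normalize_expressions(states: np.ndarray, gene_names=None):
    """Column-wise z-score of the pooled stable states (log2 levels).

    Returns ``(z, mean, sd)``; raises if any gene has zero variance,
    naming the gene.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 states to normalize")
    mean = states.mean(axis=0)
    sd = states.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        name = gene_names[bad] if gene_names is not None else f"column {bad}"
        raise ValueError(
            f"gene {name} has zero variance across states; "
            "z-scoring is undefined (was it knocked out?)"
        )
    return (states - mean) / sd, mean, sd


def apply_normalization(states, mean, sd):
    """Apply previously fitted normalization (e.g. WT stats to KO data)."""
    return (np.asarray(states, dtype=float) - mean) / sd


def zero_expression_z(mean, sd, floor: float = 1e-10):
    """z-coordinate of zero expression (level at the floor) per gene."""
    return (np.log2(floor) - np.asarray(mean)) / np.asarray(sd)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterReport:
    """Average-linkage clustering of states.

    ``labels`` are 1-based, ordered by decreasing cluster size; clusters
    ``1..n_major`` have fraction >= ``cutoff``.
    """

    labels: np.ndarray
    fractions: np.ndarray
    linkage: np.ndarray
    cut_height: float
    n_major: int
    cutoff: float


def hierarchical_clusters(
    normalized: np.ndarray,
    fraction_cutoff: float = 0.05,
    n_target: int | None = None,
) -> ClusterReport:
    """Average-linkage HCA on Euclidean distances with a fraction-based cut.

    The number of *major* clusters (fraction >= ``fraction_cutoff``) is
    read off by a persistence criterion: the tree is cut into k clusters
    for every k from 2 up to 1/cutoff (a cut into more pieces cannot be
    dominated by major clusters), and the major-cluster count that
    occurs for the most cut granularities wins, ties broken toward fewer
    clusters.  The reported labels come from the coarsest cut realizing
    that count.  ``n_target`` instead forces a cut into exactly that
    many clusters.
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 states to cluster")
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    n = X.shape[0]
    if n_target is not None:
        raw = hierarchy.fcluster(Z, t=n_target, criterion="maxclust")
    else:
        k_max = min(n - 1, int(np.ceil(1.0 / fraction_cutoff)))
        counts_by_k: dict[int, int] = {}
        for k in range(2, k_max + 1):
            lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            _, cnt = np.unique(lab, return_counts=True)
            counts_by_k[k] = int(np.sum(cnt >= fraction_cutoff * n))
        values, freq = np.unique(list(counts_by_k.values()), return_counts=True)
        mode = int(values[np.argmax(freq)])  # ties resolve to the smaller count
        k_star = min(k for k, m in counts_by_k.items() if m == mode)
        raw = hierarchy.fcluster(Z, t=k_star, criterion="maxclust")
    # relabel by decreasing size for determinism
    uniq, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.array([remap[int(v)] for v in raw])
    fractions = counts[order] / n
    n_major = int(np.sum(fractions >= fraction_cutoff))
    cut_height = float(Z[n - len(uniq), 2]) if len(uniq) < n else 0.0
    return ClusterReport(
        labels=labels,
        fractions=fractions,
        linkage=Z,
        cut_height=cut_height,
        n_major=n_major,
        cutoff=fraction_cutoff,
    )


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    coords: np.ndarray
    components: np.ndarray        # (n_components, n_genes)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_project(normalized: np.ndarray, n_components: int = 2) -> PCAResult:
    """PCA of the normalized state matrix.

    Sign convention: each component's largest-|loading| entry is positive.
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 states for PCA")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    components = pca.components_.copy()
    for c in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[c])))
        if components[c, j] < 0:
            components[c] *= -1.0
            coords[:, c] *= -1.0
    return PCAResult(
        coords=coords,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
    )


def project_onto(pca: PCAResult, normalized: np.ndarray) -> np.ndarray:
    """Project (already normalized) data onto fitted components.

    For knockout ensembles, set the knocked-out genes' columns to their
    zero-expression z-coordinate under the reference normalization first
    (:func:`zero_expression_z`).
    """
    X = np.asarray(normalized, dtype=float)
    return (X - pca.mean) @ pca.components.T


# ---------------------------------------------------------------------------
# distribution diagnostics

def state_count_distribution(counts, max_count: int | None = None) -> np.ndarray:
    """Empirical distribution of per-model stable-state counts.

    ``counts`` is an iterable of non-negative integers (or an
    ``EnsembleResult``); entry ``x`` of the result is the fraction of
    models with exactly ``x`` states.
    """
    if hasattr(counts, "state_counts"):
        counts = counts.state_counts
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no models")
    if np.any(counts < 0):
        raise ValueError("state counts must be non-negative")
    hi = int(counts.max()) if max_count is None else int(max_count)
    dist = np.bincount(counts, minlength=hi + 1)[: hi + 1].astype(float)
    return dist / counts.size


def _check_distribution(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"{name} is not a normalized distribution")
    return p


def _pad_pair(p, q):
    n = max(len(p), len(q))
    return (
        np.pad(p, (0, n - len(p))),
        np.pad(q, (0, n - len(q))),
    )


def bhattacharyya(p, q, cap: float = DISSIMILARITY_CAP) -> float:
    """Bhattacharyya distance -ln(sum sqrt(p*q)); 0 iff p == q.

    Distributions on disjoint supports (overlap coefficient 0) return the
    cap instead of infinity.  Shorter supports are zero-padded.
    """
    p = _check_distribution(p, "p")
    q = _check_distribution(q, "q")
    p, q = _pad_pair(p, q)
    bc = float(np.sum(np.sqrt(p * q)))
    if bc <= 0.0:
        return cap
    return min(max(-np.log(min(bc, 1.0)), 0.0), cap)


def kl_divergence(p, q, cap: float = DISSIMILARITY_CAP) -> float:
    """Kullback-Leibler divergence sum p ln(p/q), capped where q = 0 < p."""
    p = _check_distribution(p, "p")
    q = _check_distribution(q, "q")
    p, q = _pad_pair(p, q)
    mask = p > 0
    if np.any(q[mask] == 0):
        return cap
    return min(float(np.sum(p[mask] * np.log(p[mask] / q[mask]))), cap)


def replicate_dissimilarity(replicates, reference, metric: str = "bhattacharyya") -> float:
    """Mean pairwise distance between two replicate sets of distributions.

    With 10 replicates each this is the standard (1/100) double sum of
    Bhattacharyya distances between replicates at a test setting and
    replicates at the reference (largest) setting.
    """
    if len(replicates) < 2 or len(reference) < 2:
        raise ValueError("need at least 2 replicates per setting")
    dist = bhattacharyya if metric == "bhattacharyya" else kl_divergence
    total = 0.0
    for p in replicates:
        for q in reference:
            total += dist(p, q)
    return total / (len(replicates) * len(reference))


def histogram_support(reference_levels) -> tuple[float, float]:
    """Shared histogram range: pooled min/max of the reference replicates."""
    pooled = np.concatenate([np.ravel(a) for a in reference_levels])
    if pooled.size == 0:
        raise ValueError("no reference levels")
    return float(pooled.min()), float(pooled.max())


def expression_histogram(levels, lo: float, hi: float, n_bins: int = 50) -> np.ndarray:
    """Normalized histogram of (log2) expression levels on fixed bins.

    Values outside [lo, hi] are clipped into the edge bins so replicate
    histograms always share support.
    """
    x = np.clip(np.ravel(np.asarray(levels, dtype=float)), lo, hi)
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    if counts.sum() == 0:
        raise ValueError("empty expression sample")
    return counts / counts.sum()


def minimal_setting_scan(settings, dissimilarities, threshold: float = 5e-4):
    """Smallest setting at which the dissimilarity stops decreasing.

    Scans the (setting, dissimilarity) grid in increasing order and
    returns the first setting whose step to the next one decreases the
    dissimilarity by less than ``threshold``; returns ``None`` if the
    grid never converges.
    """
    settings = list(settings)
    D = list(dissimilarities)
    if len(settings) != len(D) or len(settings) < 2:
        raise ValueError("need matching settings/dissimilarity grids (>= 2 points)")
    if any(settings[i] >= settings[i + 1] for i in range(len(settings) - 1)):
        raise ValueError("settings grid must be strictly increasing")
    for i in range(len(settings) - 1):
        if D[i] - D[i + 1] < threshold:
            return settings[i]
    return None


# ---------------------------------------------------------------------------
# parameter differentiation between gene states

@dataclass
class ParameterDifferentiation:
    names: list[str]
    effect: np.ndarray     # standardized location difference (A - B)
    statistic: np.ndarray  # Mann-Whitney U
    pvalue: np.ndarray
    qvalue: np.ndarray     # Benjamini-Hochberg adjusted
    small_sample: bool     # fewer than 5 models in a group


def parameter_differentiation(
    params: np.ndarray,
    state_models: np.ndarray,
    labels: np.ndarray,
    cluster_a: int,
    cluster_b: int,
    names=None,
) -> ParameterDifferentiation:
    """Which parameters differ between models realizing two gene states.

    ``params`` is the (num_models, n_parameters) matrix; ``state_models``
    maps each state (row of the clustered matrix) to its model index and
    ``labels`` are the cluster labels.  For every parameter the models
    contributing at least one state to cluster A are compared with those
    contributing to cluster B by a rank-based two-sample test
    (Mann-Whitney U) plus a standardized mean difference; p-values are
    BH-adjusted across parameters.
    """
    params = np.asarray(params, dtype=float)
    state_models = np.asarray(state_models, dtype=int)
    labels = np.asarray(labels)
    models_a = np.unique(state_models[labels == cluster_a])
    models_b = np.unique(state_models[labels == cluster_b])
    if models_a.size == 0 or models_b.size == 0:
        raise ValueError("both clusters must contain at least one state")
    A = params[models_a]
    B = params[models_b]
    n_par = params.shape[1]
    effect = np.zeros(n_par)
    stat = np.zeros(n_par)
    pval = np.ones(n_par)
    identical = models_a.size == models_b.size and np.array_equal(models_a, models_b)
    for j in range(n_par):
        a, b = A[:, j], B[:, j]
        pooled = np.sqrt(0.5 * (a.var(ddof=1) if a.size > 1 else 0.0)
                         + 0.5 * (b.var(ddof=1) if b.size > 1 else 0.0))
        if identical or pooled == 0:
            effect[j] = 0.0
        else:
            effect[j] = (a.mean() - b.mean()) / pooled
        if identical or (np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]):
            stat[j] = a.size * b.size / 2.0
            pval[j] = 1.0
        else:
            res = mannwhitneyu(a, b, alternative="two-sided")
            stat[j] = float(res.statistic)
            pval[j] = float(res.pvalue)
    qval = false_discovery_control(pval, method="bh")
    if names is None:
        names = [f"param_{j}" for j in range(n_par)]
    return ParameterDifferentiation(
        names=list(names),
        effect=effect,
        statistic=stat,
        pvalue=pval,
        qvalue=qval,
        small_sample=bool(min(models_a.size, models_b.size) < 5),
    )
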