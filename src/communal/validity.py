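"""Internal cluster validity indices and the gap statistic.

Seventeen pairwise-distance indices (the roster of R's fpc
``cluster.stats``) are re-implemented here from their definitions, plus
the gap statistic with a uniform-over-feature-ranges null reference.
Each index carries an orientation (higher-better or lower-better) used
when indices are standardized and averaged into the stability map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cluster_algos import LIGHT_EFFORT, GridRuns, cluster_all_k
from .data_io import ExpressionMatrix, SubsetSeries

logger = logging.getLogger(__name__)

#: roster of metric names (fpc cluster.stats vocabulary + gap statistic)
METRICS = (
    "avg_between",
    "avg_within",
    "avg_silwidth",
    "ch_index",
    "connectivity",
    "dunn",
    "dunn2",
    "entropy",
    "g2",
    "g3",
    "gap",
    "max_diameter",
    "min_separation",
    "pearson_gamma",
    "sep_index",
    "widest_gap",
    "wcss",
    "wb_ratio",
)

PAIRWISE_METRICS = tuple(m for m in METRICS if m != "gap")

#: which direction indicates better clustering, per standard interpretation
HIGHER_BETTER = frozenset(
    {
        "avg_between",
        "avg_silwidth",
        "ch_index",
        "dunn",
        "dunn2",
        "g2",
        "gap",
        "min_separation",
        "pearson_gamma",
        "sep_index",
    }
)
LOWER_BETTER = frozenset(
    {
        "avg_within",
        "connectivity",
        "entropy",
        "g3",
        "max_diameter",
        "wcss",
        "wb_ratio",
        "widest_gap",
    }
)

ORIENTATION = {
    m: ("higher_better" if m in HIGHER_BETTER else "lower_better") for m in METRICS
}

CONNECTIVITY_L = 10  # neighbourhood size for the connectivity index
SEP_PROB = 0.1  # proportion of smallest cross-cluster gaps in sep_index


class DistanceCache:
    """Per-dataset precomputations shared by all runs on the same subset."""

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.n = self.X.shape[0]
        cond = pdist(self.X)
        self.D = squareform(cond)
        self.D2 = self.D**2
        self.n_pairs = cond.size
        self.sum_d = float(cond.sum())
        self.sum_d2 = float((cond**2).sum())
        self.sorted_d = np.sort(cond)
        self.csum_d = np.cumsum(self.sorted_d)
        # nearest-neighbour order per point (self excluded; ties by index)
        L = min(CONNECTIVITY_L, self.n - 1)
        order = np.argsort(self.D + np.diag(np.full(self.n, np.inf)), axis=1, kind="stable")
        self.nn = order[:, :L]


def _max_mst_edge(sub: np.ndarray) -> float:
    """Largest edge of a minimum spanning tree (Prim); 0 for singletons."""
    m = sub.shape[0]
    if m < 2:
        return 0.0
    dmin = sub[0].copy()
    in_tree = np.zeros(m, dtype=bool)
    in_tree[0] = True
    best = 0.0
    for _ in range(m - 1):
        dmin[in_tree] = np.inf
        j = int(np.argmin(dmin))
        best = max(best, float(dmin[j]))
        in_tree[j] = True
        np.minimum(dmin, sub[j], out=dmin)
    return best


def _score_cached(cache: DistanceCache, labels: np.ndarray) -> dict[str, float]:
    """All pairwise-distance indices for one labelling (gap excluded)."""
    n = cache.n
    labels = np.asarray(labels, dtype=int)
    uniq, inv = np.unique(labels, return_inverse=True)
    m = uniq.size
    out: dict[str, float] = {k: np.nan for k in PAIRWISE_METRICS}
    if m < 2:
        return out
    C = np.zeros((n, m))
    C[np.arange(n), inv] = 1.0
    sizes = C.sum(axis=0)
    D, D2 = cache.D, cache.D2

    M = D @ C  # M[i, c] = sum of distances from i to members of c
    within_sum_c = (M * C).sum(axis=0) / 2.0  # per-cluster within-pair sums
    within_pairs_c = sizes * (sizes - 1) / 2.0
    w_sum = float(within_sum_c.sum())
    w_pairs = float(within_pairs_c.sum())
    b_pairs = cache.n_pairs - w_pairs
    b_sum = cache.sum_d - w_sum

    if w_pairs > 0:
        out["avg_within"] = w_sum / w_pairs
    if b_pairs > 0:
        out["avg_between"] = b_sum / b_pairs
    if w_pairs > 0 and b_pairs > 0 and out["avg_between"] > 0:
        out["wb_ratio"] = out["avg_within"] / out["avg_between"]

    # silhouette
    own = M[np.arange(n), inv]
    size_own = sizes[inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = own / (size_own - 1)
    Mb = M / sizes[None, :]
    Mb[np.arange(n), inv] = np.inf
    b = Mb.min(axis=1)
    s = np.where(size_own > 1, (b - a) / np.maximum(a, b), 0.0)
    s = np.where(np.maximum(a, b) > 0, s, 0.0)
    out["avg_silwidth"] = float(np.mean(s))

    # sums-of-squares family
    M2 = D2 @ C
    ss_c = (M2 * C).sum(axis=0) / (2.0 * sizes)  # per-cluster SS around centroid
    W = float(ss_c.sum())
    T = cache.sum_d2 / n
    B = max(T - W, 0.0)
    out["wcss"] = W
    if m > 1 and n > m and W > 0:
        out["ch_index"] = (B / (m - 1)) / (W / (n - m))

    # entropy of cluster proportions
    p = sizes / n
    out["entropy"] = float(-(p * np.log(p)).sum())

    # separations and diameters
    same = inv[:, None] == inv[None, :]
    big = cache.D.max() + 1.0
    off = ~np.eye(n, dtype=bool)
    within_mask = same & off
    if within_mask.any():
        out["max_diameter"] = float(D[within_mask].max())
    else:
        out["max_diameter"] = 0.0
    between_mask = ~same
    out["min_separation"] = float(D[between_mask].min())
    if out["max_diameter"] > 0:
        out["dunn"] = out["min_separation"] / out["max_diameter"]

    # dunn2: min mean between-cluster distance / max mean within-cluster distance
    pair_sums = C.T @ D @ C
    denom = np.outer(sizes, sizes)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_means = pair_sums / denom
    between_means = pair_means[~np.eye(m, dtype=bool)]
    with np.errstate(invalid="ignore", divide="ignore"):
        within_means = np.where(
            within_pairs_c > 0, within_sum_c / within_pairs_c, np.nan
        )
    if np.any(within_pairs_c > 0):
        max_within_mean = float(np.nanmax(within_means))
        if max_within_mean > 0:
            out["dunn2"] = float(between_means.min()) / max_within_mean

    # connectivity: penalise nearest neighbours outside the cluster
    nn = cache.nn
    L = nn.shape[1]
    mismatch = inv[nn] != inv[:, None]
    weights = 1.0 / np.arange(1, L + 1)
    out["connectivity"] = float((mismatch * weights[None, :]).sum())

    # G2: concordance between within/between status and distance magnitude
    iu = np.triu_indices(n, 1)
    same_cond = same[iu]
    d_cond = D[iu]
    w_d = d_cond[same_cond]
    b_d = np.sort(d_cond[~same_cond])
    if w_d.size and b_d.size:
        lo = np.searchsorted(b_d, w_d, side="left")
        hi = np.searchsorted(b_d, w_d, side="right")
        s_minus = float(lo.sum())  # between < within: discordant
        s_plus = float((b_d.size - hi).sum())  # between > within: concordant
        if s_plus + s_minus > 0:
            out["g2"] = (s_plus - s_minus) / (s_plus + s_minus)

    # G3: within-pair sum against the best/worst achievable sums
    mw = int(w_pairs)
    if 0 < mw < cache.n_pairs:
        s_min = float(cache.csum_d[mw - 1])
        s_max = float(cache.csum_d[-1] - cache.csum_d[cache.n_pairs - mw - 1])
        if s_max > s_min:
            out["g3"] = (w_sum - s_min) / (s_max - s_min)

    # Pearson gamma: correlation of distances with the different-cluster indicator
    P = cache.n_pairs
    mean_d = cache.sum_d / P
    mean_i = b_pairs / P
    cov = b_sum / P - mean_d * mean_i
    var_d = cache.sum_d2 / P - mean_d**2
    var_i = mean_i - mean_i**2
    if var_d > 0 and var_i > 0:
        out["pearson_gamma"] = cov / math.sqrt(var_d * var_i)

    # separation index: mean of the smallest fraction of cross-cluster gaps
    Dmask = D + big * same
    nearest_other = Dmask.min(axis=1)
    nsep = max(1, int(round(SEP_PROB * n)))
    out["sep_index"] = float(np.sort(nearest_other)[:nsep].mean())

    # widest within-cluster gap: the largest MST edge over all clusters
    wg = 0.0
    for c in range(m):
        members = np.where(inv == c)[0]
        if members.size > 1:
            wg = max(wg, _max_mst_edge(D[np.ix_(members, members)]))
    out["widest_gap"] = wg
    return out


def score_run(data: np.ndarray, labels: np.ndarray, k: int) -> dict[str, float]:
    """All 17 pairwise-distance validity indices for one clustering.

    ``k`` is the requested cluster count; indices are computed on the
    clusters actually present.  Indices undefined for a degenerate
    labelling are returned as NaN (absent), never coerced to 0.
    """
    labels = np.asarray(labels, dtype=int)
    X = np.asarray(data, dtype=float)
    if labels.size != X.shape[0]:
        raise ValueError("labels length must equal number of samples")
    if not (2 <= k <= X.shape[0] - 1):
        raise ValueError(f"k={k} outside [2, {X.shape[0] - 1}]")
    return _score_cached(DistanceCache(X), labels)


def pooled_within_dispersion(D2: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (within-cluster sum of squared distances)/(2 n_c).

    Equals the total within-cluster sum of squares around centroids when
    distances are Euclidean.
    """
    labels = np.asarray(labels, dtype=int)
    uniq, inv = np.unique(labels, return_inverse=True)
    n = labels.size
    C = np.zeros((n, uniq.size))
    C[np.arange(n), inv] = 1.0
    sizes = C.sum(axis=0)
    per_cluster = ((D2 @ C) * C).sum(axis=0)  # ordered-pair sums
    return float((per_cluster / (2.0 * sizes)).sum())


class GapResult(NamedTuple):
    gap: float
    se: float


def gap_statistic(
    data: np.ndarray,
    labels_fn: Callable[[np.ndarray, int], np.ndarray],
    k: int,
    B: int = 50,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> GapResult:
    """Gap(k) = mean_b log W*_kb - log W_k, uniform-box null reference.

    Reference datasets are drawn uniformly over the observed per-feature
    ranges and clustered with ``labels_fn(ref_data, k)``.  The standard
    error sd(log W*) * sqrt(1 + 1/B) is returned alongside the gap.
    """
    X = np.asarray(data, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    if np.all(maxs - mins == 0):
        raise ValueError("degenerate data: zero range in every feature")
    D2 = squareform(pdist(X)) ** 2
    if labels is None:
        labels = labels_fn(X, k)
    W = pooled_within_dispersion(D2, labels)
    if W <= 0:
        raise ValueError("zero within-cluster dispersion; gap undefined (log W)")
    log_w_star = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        ref = rng.uniform(mins, maxs, size=X.shape)
        ref_labels = labels_fn(ref, k)
        w_star = pooled_within_dispersion(squareform(pdist(ref)) ** 2, ref_labels)
        log_w_star[b] = np.log(w_star) if w_star > 0 else np.nan
    log_w_star = log_w_star[np.isfinite(log_w_star)]
    if log_w_star.size == 0:
        raise ValueError("all reference dispersions degenerate")
    gap = float(log_w_star.mean() - np.log(W))
    sd = float(log_w_star.std(ddof=0)) if log_w_star.size > 1 else 0.0
    se = sd * math.sqrt(1.0 + 1.0 / log_w_star.size)
    return GapResult(gap=gap, se=se)


@dataclass
class ValidityTensor:
    """values[metric, algorithm, k, subset]; NaN marks absent cells."""

    values: np.ndarray
    metrics: list[str]
    algorithms: list[str]
    k_values: list[int]
    subset_sizes: list[int]
    gap_se: np.ndarray | None = field(default=None, repr=False)

    def index(self, metric: str) -> int:
        return self.metrics.index(metric)

    def slab(self, metric: str, algorithm: str) -> np.ndarray:
        """K x n matrix for one (metric, algorithm)."""
        return self.values[self.metrics.index(metric), self.algorithms.index(algorithm)]

    def get(self, metric: str, algorithm: str, k: int, subset_size: int) -> float:
        return float(
            self.values[
                self.metrics.index(metric),
                self.algorithms.index(algorithm),
                self.k_values.index(k),
                self.subset_sizes.index(subset_size),
            ]
        )

    def cell_table(self, metrics: list[str] | None = None) -> np.ndarray:
        """(n_cells, n_metrics) matrix of values over all (algorithm, k, subset)."""
        metrics = metrics or self.metrics
        idx = [self.metrics.index(m) for m in metrics]
        sub = self.values[idx]  # m x a x k x s
        return sub.reshape(len(idx), -1).T


def score_grid(
    runs: GridRuns,
    m: ExpressionMatrix,
    subsets: SubsetSeries,
    *,
    gap_b: int = 50,
    seed: int = 0,
    include_gap: bool = True,
    metrics: tuple[str, ...] = METRICS,
) -> ValidityTensor:
    """Score every grid run with every validity index.

    Distances are computed on the same variable subset used for
    clustering.  For the gap statistic, the B reference datasets of a
    subset are shared across algorithms and K: each reference draw is
    clustered once per algorithm over the whole K range (with reduced
    stochastic effort; see docs), which leaves the Monte-Carlo averaging
    over draws intact while avoiding redundant reclustering.
    """
    metrics = tuple(mt for mt in metrics if include_gap or mt != "gap")
    algos = runs.algorithms
    kv = runs.k_values
    sizes = runs.subset_sizes
    shape = (len(metrics), len(algos), len(kv), len(sizes))
    values = np.full(shape, np.nan)
    gap_se = np.full(shape[1:], np.nan)
    want_gap = "gap" in metrics
    gap_idx = metrics.index("gap") if want_gap else -1

    for si, size in enumerate(sizes):
        X = m.values[:, subsets.indices(si)]
        cache = DistanceCache(X)
        for ai, alg in enumerate(algos):
            for ki, k in enumerate(kv):
                run = runs.get(alg, size, k)
                if run is None:
                    continue
                scores = _score_cached(cache, run.labels)
                for mi, met in enumerate(metrics):
                    if met != "gap":
                        values[mi, ai, ki, si] = scores[met]
        if want_gap:
            _fill_gap(
                values[gap_idx], gap_se, si, X, cache, runs, algos, kv, gap_b, seed
            )
    return ValidityTensor(
        values=values,
        metrics=list(metrics),
        algorithms=list(algos),
        k_values=list(kv),
        subset_sizes=list(sizes),
        gap_se=gap_se if want_gap else None,
    )


def _fill_gap(
    gap_values: np.ndarray,
    gap_se: np.ndarray,
    si: int,
    X: np.ndarray,
    cache: DistanceCache,
    runs: GridRuns,
    algos: list[str],
    kv: list[int],
    B: int,
    seed: int,
) -> None:
    """Gap statistic for all (algorithm, K) of one subset, sharing reference draws."""
    size = runs.subset_sizes[si]
    mins, maxs = X.min(axis=0), X.max(axis=0)
    if np.all(maxs - mins == 0):
        return
    log_w_obs = np.full((len(algos), len(kv)), np.nan)
    for ai, alg in enumerate(algos):
        for ki, k in enumerate(kv):
            run = runs.get(alg, size, k)
            if run is None:
                continue
            w = pooled_within_dispersion(cache.D2, run.labels)
            if w > 0:
                log_w_obs[ai, ki] = np.log(w)
    log_w_star = np.full((len(algos), len(kv), B), np.nan)
    for b in range(B):
        rng = np.random.default_rng([seed, si, b])
        ref = rng.uniform(mins, maxs, size=X.shape)
        Dref = squareform(pdist(ref))
        D2ref = Dref**2
        sub_seed = int(rng.integers(2**31))
        for ai, alg in enumerate(algos):
            try:
                by_k = cluster_all_k(ref, Dref, alg, kv, sub_seed, **LIGHT_EFFORT)
            except Exception as exc:  # pragma: no cover
                logger.warning("gap reference clustering failed (%s): %s", alg, exc)
                continue
            for ki, k in enumerate(kv):
                w = pooled_within_dispersion(D2ref, by_k[k])
                if w > 0:
                    log_w_star[ai, ki, b] = np.log(w)
    with np.errstate(invalid="ignore"):
        mean_star = np.nanmean(log_w_star, axis=2)
        sd_star = np.nanstd(log_w_star, axis=2, ddof=0)
        counts = np.sum(np.isfinite(log_w_star), axis=2)
    gap_values[:, :, si] = mean_star - log_w_obs
    with np.errstate(divide="ignore", invalid="ignore"):
        gap_se[:, :, si] = sd_star * np.sqrt(1.0 + 1.0 / counts)
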