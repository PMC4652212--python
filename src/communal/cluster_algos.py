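"""Eight hard-partition clustering algorithms under a single contract.

Every algorithm takes a samples-by-variables matrix and a requested
cluster count K, and returns exactly one integer label in 1..K per
sample.  Only algorithms that accept a user-specified K belong here;
soft/fuzzy methods that may return a different number of clusters are
deliberately excluded.

Roster:

========== ==========================================================
name        method
========== ==========================================================
hierarchical  agglomerative, Ward objective on Euclidean distances
agnes         agglomerative nesting; Ward update applied to squared
              distances (the classic Ward.D convention), so it can
              differ from ``hierarchical`` (Ward.D2) in merge order
diana         divisive analysis: repeatedly split the largest-diameter
              cluster via the splinter procedure
kmeans        Lloyd iterations, squared Euclidean, multiple restarts
pam           partitioning around medoids (BUILD + SWAP)
clara         repeated PAM on random sub-samples, best replicate kept
som           self-organizing map on a 1 x K linear grid, batch trained
sota          self-organizing tree algorithm: binary tree growing by
              cell division of the most heterogeneous leaf
========== ==========================================================

All deterministic given (data, algorithm, k, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix, SubsetSeries

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "hierarchical",
    "kmeans",
    "diana",
    "som",
    "sota",
    "pam",
    "clara",
    "agnes",
)

#: reduced-effort settings used for null-reference clusterings (gap statistic)
LIGHT_EFFORT = {"n_init": 1, "clara_reps": 2, "som_epochs": 10}


@dataclass
class ClusterRun:
    """One (algorithm, subset size, K) labelling of all samples."""

    algorithm: str
    subset_size: int
    k: int
    labels: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if np.unique(self.labels).size < self.k and "degenerate" not in self.flags:
            self.flags.append("degenerate")

    @property
    def n_clusters_found(self) -> int:
        return int(np.unique(self.labels).size)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


# ---------------------------------------------------------------------------
# individual algorithms (internal; operate on data matrix X and/or distance D)
# ---------------------------------------------------------------------------


def _ward_tree(D: np.ndarray, squared: bool) -> np.ndarray:
    """Linkage matrix for Ward agglomeration.

    ``squared=False`` is the Ward.D2 convention (update on Euclidean
    distances); ``squared=True`` applies the Lance-Williams Ward update to
    squared distances (Ward.D convention).  Merge order can differ.
    """
    cond = squareform(D, checks=False)
    if squared:
        cond = cond**2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on non-Euclidean input
        return linkage(cond, method="ward")


def _cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    labels = fcluster(Z, t=k, criterion="maxclust")
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..m in order of first appearance (deterministic)."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def _diana_all_k(D: np.ndarray, k_max: int) -> dict[int, np.ndarray]:
    """Divisive analysis; returns labels for every cluster count 2..k_max.

    At each step the cluster with the largest diameter is split: the
    splinter seed is the member with the largest average dissimilarity to
    the rest; members move to the splinter group while the gain (average
    dissimilarity to the remaining old group minus average dissimilarity
    to the splinter group) is positive.
    """
    n = D.shape[0]
    clusters: list[np.ndarray] = [np.arange(n)]
    out: dict[int, np.ndarray] = {}
    while len(clusters) < k_max:
        diams = [
            D[np.ix_(c, c)].max() if c.size > 1 else 0.0 for c in clusters
        ]
        target = int(np.argmax(diams))
        if diams[target] <= 0.0:
            # all remaining clusters are point-coincident; split largest by index
            sizes = [c.size for c in clusters]
            target = int(np.argmax(sizes))
            if clusters[target].size < 2:
                break
        c = clusters[target]
        sub = D[np.ix_(c, c)]
        m = c.size
        avg = sub.sum(axis=1) / (m - 1)
        splinter = [int(np.argmax(avg))]
        rest = [i for i in range(m) if i != splinter[0]]
        while len(rest) > 1:
            rest_arr = np.array(rest)
            spl_arr = np.array(splinter)
            d_rest = sub[np.ix_(rest_arr, rest_arr)].sum(axis=1) / (len(rest) - 1)
            d_spl = sub[np.ix_(rest_arr, spl_arr)].mean(axis=1)
            gain = d_rest - d_spl
            best = int(np.argmax(gain))
            if gain[best] <= 0:
                break
            splinter.append(rest.pop(best))
        clusters[target] = c[np.array(rest)]
        clusters.append(c[np.array(sorted(splinter))])
        k = len(clusters)
        labels = np.empty(n, dtype=int)
        for i, cl in enumerate(clusters, start=1):
            labels[cl] = i
        out[k] = _canonical_labels(labels)
    # pad any remaining counts (unsplittable data) with the last labelling
    for k in range(len(clusters) + 1, k_max + 1):
        out[k] = out[max(out)] if out else np.ones(n, dtype=int)
    return out


def _pam(D: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, float]:
    """PAM on a precomputed distance matrix; returns (medoid indices, total cost).

    BUILD greedily adds the medoid with the largest dissimilarity decrease;
    SWAP evaluates every (medoid, non-medoid) exchange per pass and applies
    the single best improving swap until none improves.
    """
    n = D.shape[0]
    if k >= n:
        return np.arange(n), 0.0
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[medoids[0]].copy()
    for _ in range(1, k):
        gain = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        j = int(np.argmax(gain))
        medoids.append(j)
        np.minimum(dnear, D[j], out=dnear)
    med = np.array(medoids)
    for _ in range(max_iter):
        dm = D[med]  # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        idx = np.arange(n)
        nearest = order[0]
        dnear = dm[nearest, idx]
        dsecond = dm[order[1], idx]
        mn = np.minimum(D, dnear[:, None])  # mn[i, j] = min(d_ij, dnear_i)
        delta_shared = mn.sum(axis=0) - dnear.sum()
        ms = np.minimum(D, dsecond[:, None]) - mn
        onehot = np.zeros((k, n))
        onehot[nearest, idx] = 1.0
        delta = delta_shared[None, :] + onehot @ ms  # k x n swap costs
        delta[:, med] = np.inf
        m_idx, j = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[m_idx, j] >= -1e-10:
            break
        med[m_idx] = j
    dm = D[med]
    nearest = np.argmin(dm, axis=0)
    cost = float(dm[nearest, np.arange(n)].sum())
    return med, cost


def _labels_from_medoids(D: np.ndarray, med: np.ndarray) -> np.ndarray:
    return _canonical_labels(np.argmin(D[med], axis=0) + 1)


def _clara(
    D: np.ndarray, k: int, rng: np.random.Generator, n_reps: int = 5
) -> np.ndarray:
    """CLARA: PAM on random sub-samples of size min(N, 40 + 2k)."""
    n = D.shape[0]
    s = min(n, 40 + 2 * k)
    best_cost, best_med = np.inf, None
    for _ in range(n_reps):
        sub = np.sort(rng.choice(n, size=s, replace=False))
        med_local, _ = _pam(D[np.ix_(sub, sub)], k)
        med = sub[med_local]
        cost = float(D[med, :].min(axis=0).sum())
        if cost < best_cost:
            best_cost, best_med = cost, med
    return _labels_from_medoids(D, best_med)


def _first_pc_projection(X: np.ndarray, n_iter: int = 15) -> np.ndarray:
    """Projection of centred data on its first principal direction (power iteration)."""
    Xc = X - X.mean(axis=0)
    v = Xc.sum(axis=0)
    if not np.any(v):
        v = np.ones(X.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        w = Xc.T @ (Xc @ v)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            break
        v = w / nrm
    return Xc @ v


def _som(X: np.ndarray, k: int, epochs: int = 100) -> np.ndarray:
    """Batch-trained SOM on a 1 x k linear grid; cluster = best-matching unit.

    Units are initialised as contiguous-group means along the first
    principal direction; the Gaussian neighbourhood radius decays linearly
    over a coarse ordering phase and is then held small for fine tuning
    (the two-phase schedule of classic SOM training).
    """
    n = X.shape[0]
    proj = _first_pc_projection(X)
    order = np.argsort(proj, kind="stable")
    groups = np.array_split(order, k)
    W = np.vstack([X[g].mean(axis=0) if g.size else X.mean(axis=0) for g in groups])
    grid = np.arange(k, dtype=float)
    gd2 = (grid[:, None] - grid[None, :]) ** 2
    ordering_epochs = max(1, epochs // 2)
    x_sq = (X**2).sum(axis=1)
    bmu = np.zeros(n, dtype=int)
    for ep in range(epochs):
        if ep < ordering_epochs:
            sigma = max(k / 2.0 * (1 - ep / ordering_epochs), 0.3)
        else:
            sigma = 0.3
        d2 = x_sq[:, None] - 2 * X @ W.T + (W**2).sum(axis=1)[None, :]
        bmu = np.argmin(d2, axis=1)
        H = np.exp(-gd2 / (2 * sigma**2))
        S = np.zeros((k, n))
        S[bmu, np.arange(n)] = 1.0
        num = H @ (S @ X)
        den = H @ S.sum(axis=1)
        ok = den > 1e-12
        W[ok] = num[ok] / den[ok, None]
    return _canonical_labels(bmu + 1)


def _split_leaf_two_means(
    X: np.ndarray, D: np.ndarray, members: np.ndarray, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Cell division: partition a leaf into two daughters.

    Daughter centroids start at the leaf's two mutually farthest members,
    then alternate assignment/centroid updates restricted to the leaf.
    """
    sub = D[np.ix_(members, members)]
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    c = np.vstack([X[members[i]], X[members[j]]])
    Xm = X[members]
    assign = np.zeros(members.size, dtype=int)
    for _ in range(max_iter):
        d2 = ((Xm[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        new = np.argmin(d2, axis=1)
        if np.array_equal(new, assign) and _ > 0:
            break
        assign = new
        for g in (0, 1):
            if np.any(assign == g):
                c[g] = Xm[assign == g].mean(axis=0)
    if assign.min() == assign.max():  # degenerate: force the farthest pair apart
        assign[:] = 0
        assign[j] = 1
    return members[assign == 0], members[assign == 1]


def _sota_all_k(X: np.ndarray, D: np.ndarray, k_max: int) -> dict[int, np.ndarray]:
    """Self-organizing tree: grow a binary tree until k_max leaves.

    The leaf with the highest resource (mean member-to-centroid Euclidean
    distance) divides into two daughter cells; labels are recorded at every
    intermediate leaf count.
    """
    n = X.shape[0]
    leaves: list[np.ndarray] = [np.arange(n)]
    out: dict[int, np.ndarray] = {}
    while len(leaves) < k_max:
        res = []
        for c in leaves:
            if c.size < 2:
                res.append(-1.0)
            else:
                mu = X[c].mean(axis=0)
                res.append(float(np.sqrt(((X[c] - mu) ** 2).sum(axis=1)).mean()))
        target = int(np.argmax(res))
        if res[target] < 0:
            break
        a, b = _split_leaf_two_means(X, D, leaves[target])
        leaves[target] = a
        leaves.append(b)
        labels = np.empty(n, dtype=int)
        for i, c in enumerate(leaves, start=1):
            labels[c] = i
        out[len(leaves)] = _canonical_labels(labels)
    for k in range(len(leaves) + 1, k_max + 1):
        out[k] = out[max(out)] if out else np.ones(n, dtype=int)
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def cluster_all_k(
    X: np.ndarray,
    D: np.ndarray,
    algorithm: str,
    k_values: list[int],
    seed: int,
    *,
    n_init: int = 10,
    clara_reps: int = 5,
    som_epochs: int = 100,
) -> dict[int, np.ndarray]:
    """Labels (1..k arrays) for every requested K, sharing work across K.

    Tree-structured algorithms (hierarchical, agnes, diana, sota) build one
    tree and read off all K; the partitioning algorithms run per K.
    """
    k_values = sorted(k_values)
    k_max = k_values[-1]
    n = X.shape[0]
    if k_values[0] < 2 or k_max > n - 1:
        raise ValueError(f"k must lie in [2, {n - 1}], got {k_values}")
    if algorithm in ("hierarchical", "agnes"):
        Z = _ward_tree(D, squared=(algorithm == "agnes"))
        return {k: _cut_tree(Z, k) for k in k_values}
    if algorithm == "diana":
        all_k = _diana_all_k(D, k_max)
        return {k: all_k[k] for k in k_values}
    if algorithm == "sota":
        all_k = _sota_all_k(X, D, k_max)
        return {k: all_k[k] for k in k_values}
    out = {}
    for k in k_values:
        if algorithm == "kmeans":
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**31))
            out[k] = _canonical_labels(km.fit_predict(X) + 1)
        elif algorithm == "pam":
            med, _ = _pam(D, k)
            out[k] = _labels_from_medoids(D, med)
        elif algorithm == "clara":
            rng = np.random.default_rng([seed, k])
            out[k] = _clara(D, k, rng, n_reps=clara_reps)
        elif algorithm == "som":
            out[k] = _som(X, k, epochs=som_epochs)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
    return out


def run_algorithm(
    data: np.ndarray,
    algorithm: str,
    k: int,
    seed: int = 0,
    *,
    subset_size: int | None = None,
    **effort,
) -> ClusterRun:
    """Cluster ``data`` (samples x variables) into exactly ``k`` groups.

    Deterministic given (data, algorithm, k, seed).  Raises for k outside
    [2, n_samples - 1]; a run that cannot realise all k clusters is
    returned with a ``degenerate`` flag rather than failing.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D (samples x variables)")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite values")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    D = squareform(pdist(X))
    labels = cluster_all_k(X, D, algorithm, [k], seed, **effort)[k]
    return ClusterRun(
        algorithm=algorithm,
        subset_size=subset_size if subset_size is not None else X.shape[1],
        k=k,
        labels=labels,
    )


@dataclass
class GridRuns:
    """All ClusterRuns of a grid, keyed by (algorithm, subset_size, k)."""

    runs: dict[tuple[str, int, int], ClusterRun]
    algorithms: list[str]
    subset_sizes: list[int]
    k_values: list[int]
    failures: list[tuple[str, int, int, str]] = field(default_factory=list)

    def get(self, algorithm: str, subset_size: int, k: int) -> ClusterRun | None:
        return self.runs.get((algorithm, subset_size, k))

    def __len__(self) -> int:
        return len(self.runs)


def run_grid(
    m: ExpressionMatrix,
    subsets: SubsetSeries,
    algorithms: list[str] | tuple[str, ...] = ALGORITHMS,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    **effort,
) -> GridRuns:
    """One ClusterRun per (algorithm x subset x K).

    Individual run failures are recorded in ``failures`` and skipped;
    downstream consumers treat the missing cells as absent.
    """
    algorithms = list(algorithms)
    if not algorithms:
        raise ValueError("algorithm list must not be empty")
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo < 2 or hi > m.n_samples - 1 or lo > hi:
        raise ValueError(f"k range [{lo}, {hi}] outside [2, {m.n_samples - 1}]")
    k_values = list(range(lo, hi + 1))
    runs: dict[tuple[str, int, int], ClusterRun] = {}
    failures: list[tuple[str, int, int, str]] = []
    for si in range(len(subsets)):
        size = subsets.sizes[si]
        X = m.values[:, subsets.indices(si)]
        D = squareform(pdist(X))
        for alg in algorithms:
            try:
                by_k = cluster_all_k(X, D, alg, k_values, seed, **effort)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("grid run failed: %s subset=%d: %s", alg, size, exc)
                for k in k_values:
                    failures.append((alg, size, k, str(exc)))
                continue
            for k, labels in by_k.items():
                runs[(alg, size, k)] = ClusterRun(
                    algorithm=alg, subset_size=size, k=k, labels=labels
                )
    return GridRuns(
        runs=runs,
        algorithms=algorithms,
        subset_sizes=list(subsets.sizes),
        k_values=k_values,
        failures=failures,
    )
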