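"""Local roster optimization: drop tiny-cluster-prone algorithms, drop
monotonic validity metrics, then pick a low-redundancy final metric set.

The rationale: algorithms that frequently carve off clusters with fewer
than ``min_size`` members desynchronise the K at which the major splits
of the data appear, and validity metrics that rank K monotonically carry
a bias toward low or high K and hence no peak information.  Both are
detected from the grid itself, so the rosters adapt to each dataset.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cluster_algos import GridRuns
from .validity import ValidityTensor

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 3


@dataclass
class TinyClusterProfile:
    """Per-algorithm percent of grid runs with any cluster below min_size."""

    percents: dict[str, float]
    min_size: int
    retained: list[str]


@dataclass
class MonotonicityProfile:
    """Per-metric percent of (algorithm, subset) K-sequences that are monotone."""

    percents: dict[str, float]
    retained: list[str]


def tiny_cluster_percents(runs: GridRuns, min_size: int = DEFAULT_MIN_SIZE) -> dict[str, float]:
    """Percent (0-100) of an algorithm's runs producing any cluster with < min_size members."""
    out: dict[str, float] = {}
    for alg in runs.algorithms:
        flags = []
        for size in runs.subset_sizes:
            for k in runs.k_values:
                run = runs.get(alg, size, k)
                if run is None:
                    continue
                flags.append(bool((run.cluster_sizes() < min_size).any()))
        out[alg] = 100.0 * np.mean(flags) if flags else np.nan
    return out


def filter_algorithms(
    runs: GridRuns, min_size: int = DEFAULT_MIN_SIZE
) -> TinyClusterProfile:
    """Remove algorithms whose tiny-cluster percent is strictly above the mean.

    At least one algorithm is always retained (with all-equal percents the
    strict rule removes nothing).
    """
    if len(runs.algorithms) < 2:
        raise ValueError("algorithm filtering needs at least 2 algorithms")
    percents = tiny_cluster_percents(runs, min_size)
    vals = np.array([percents[a] for a in runs.algorithms])
    mean = float(np.nanmean(vals))
    retained = [a for a in runs.algorithms if not (percents[a] > mean)]
    if not retained:  # unreachable with the strict rule; defensive
        retained = [min(runs.algorithms, key=lambda a: percents[a])]
    return TinyClusterProfile(percents=percents, min_size=min_size, retained=retained)


def is_monotone(seq: np.ndarray) -> bool:
    """Non-strict monotonicity (entirely non-increasing or non-decreasing).

    Constant sequences count as monotone.  NaNs are dropped first;
    sequences with fewer than 2 finite values are not classified.
    """
    v = np.asarray(seq, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("monotonicity undefined for <2 values")
    d = np.diff(v)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def monotonic_percents(t: ValidityTensor) -> dict[str, float]:
    """Percent of (algorithm, subset) K-sequences of each metric that are monotone."""
    out: dict[str, float] = {}
    for mi, met in enumerate(t.metrics):
        flags = []
        for ai in range(len(t.algorithms)):
            for si in range(len(t.subset_sizes)):
                seq = t.values[mi, ai, :, si]
                seq = seq[np.isfinite(seq)]
                if seq.size < 2:
                    continue
                flags.append(is_monotone(seq))
        out[met] = 100.0 * np.mean(flags) if flags else np.nan
    return out


def filter_metrics(t: ValidityTensor) -> MonotonicityProfile:
    """Remove metrics whose monotonic percent is strictly above the median."""
    percents = monotonic_percents(t)
    vals = np.array([percents[m] for m in t.metrics])
    med = float(np.nanmedian(vals))
    retained = [m for m in t.metrics if not (percents[m] > med)]
    return MonotonicityProfile(percents=percents, retained=retained)


def metric_correlations(t: ValidityTensor, metrics: list[str]) -> np.ndarray:
    """Pairwise Pearson correlations over all (algorithm, K, subset) cells.

    Pairwise-complete: each correlation uses the cells finite for both
    metrics.
    """
    table = t.cell_table(metrics)  # cells x metrics
    p = len(metrics)
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            ok = np.isfinite(table[:, i]) & np.isfinite(table[:, j])
            if ok.sum() < 3:
                r = 0.0
            else:
                xi, xj = table[ok, i], table[ok, j]
                if xi.std() == 0 or xj.std() == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(xi, xj)[0, 1])
            R[i, j] = R[j, i] = r
    return R


def select_final_metrics(
    t: ValidityTensor,
    retained: list[str],
    n_groups: int,
    exhaustive_limit: int = 100_000,
) -> list[str]:
    """Cluster retained metrics by mutual correlation; pick one per group.

    Metrics are hierarchically clustered (average linkage on 1 - |r|) into
    ``n_groups`` groups, and the cross-group selection minimising the mean
    absolute pairwise correlation of the chosen set is returned
    (exhaustive over per-group choices up to ``exhaustive_limit``
    combinations, greedy beyond).
    """
    if len(retained) < 2:
        warnings.warn("fewer than 2 retained metrics; returning unchanged")
        return list(retained)
    if n_groups > len(retained):
        raise ValueError(
            f"n_groups={n_groups} exceeds the {len(retained)} retained metrics"
        )
    if n_groups == len(retained):
        return list(retained)
    R = metric_correlations(t, retained)
    dist = 1.0 - np.abs(R)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    groups = fcluster(Z, t=n_groups, criterion="maxclust")
    members = [
        [i for i in range(len(retained)) if groups[i] == g]
        for g in sorted(set(groups))
    ]

    def set_cost(idx: tuple[int, ...]) -> float:
        if len(idx) < 2:
            return 0.0
        sub = np.abs(R[np.ix_(idx, idx)])
        p = len(idx)
        return float((sub.sum() - p) / (p * (p - 1)))

    n_comb = int(np.prod([len(g) for g in members]))
    if n_comb <= exhaustive_limit:
        best = min(itertools.product(*members), key=set_cost)
    else:  # greedy: grow the set group by group
        chosen: list[int] = []
        for g in members:
            chosen.append(min(g, key=lambda i: set_cost(tuple(chosen + [i]))))
        best = tuple(chosen)
    return [retained[i] for i in sorted(best)]


def selection_report(
    tiny: TinyClusterProfile, mono: MonotonicityProfile, final: list[str]
) -> str:
    """TSV report mirroring the monotonicity / tiny-cluster tables."""
    lines = ["entity\tkind\tpercent\tretained\tfinal"]
    for met, pct in mono.percents.items():
        lines.append(
            f"{met}\tmetric\t{pct:.1f}\t{int(met in mono.retained)}\t{int(met in final)}"
        )
    for alg, pct in tiny.percents.items():
        lines.append(f"{alg}\talgorithm\t{pct:.1f}\t{int(alg in tiny.retained)}\t")
    return "\n".join(lines) + "\n"
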