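"""Scikit-learn-style estimators wrapping the full pipeline.

:class:`CommunalMap` is the main entry point: ``fit(X)`` on a
samples-by-variables matrix runs the clustering grid over nested
variance-ranked variable subsets and a range of K, scores every run
with the validity-index roster, locally optimises the algorithm and
metric rosters, and exposes the K x n stability map with its marked
optima as fitted attributes.

:class:`CoreClusterer` produces consensus ("core") labels at one chosen
(K, subset size) by re-keying per-algorithm labels and majority voting;
samples without sufficient agreement get label 0.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import selection
from .cluster_algos import ALGORITHMS, run_algorithm, run_grid
from .commap import build_map
from .core_assign import core_clusters, find_blocks, rekey
from .data_io import ExpressionMatrix, SubsetSeries, make_subsets, rank_by_variance
from .validity import METRICS, score_grid

__all__ = ["CommunalMap", "CoreClusterer"]


def _as_expression_matrix(X) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    arr = check_array(X, dtype=float, ensure_all_finite=True, ensure_min_samples=3)
    return ExpressionMatrix(
        values=arr,
        sample_ids=[f"S{i}" for i in range(arr.shape[0])],
        variable_ids=[f"V{j}" for j in range(arr.shape[1])],
    )


class CommunalMap(BaseEstimator):
    """Map cluster-number stability over algorithms, metrics and subsets.

    Parameters
    ----------
    k_range : (int, int), default=(2, 10)
        Inclusive range of cluster counts K to evaluate.
    subset_sizes : list of int, optional
        Explicit nested subset sizes (variables, ranked by descending
        variance).  Mutually exclusive with ``subset_step``.
    subset_step : int, optional
        Build subsets of size step, 2*step, ... up to all variables.
        When neither is given, five evenly spaced subsets are used.
    algorithms : tuple of str
        Clustering roster (see :data:`communal.cluster_algos.ALGORITHMS`).
    n_metric_groups : int, default=4
        Number of correlation groups from which the final metrics are
        drawn (one representative per group).
    min_cluster_size : int, default=3
        Clusters smaller than this are "tiny"; algorithms producing them
        in more than the mean fraction of runs are dropped.
    gap_b : int, default=50
        Reference replicates for the gap statistic.
    include_gap : bool, default=True
        Whether the gap statistic joins the metric roster.
    random_state : int, default=0
        Seed for all stochastic algorithms and gap references.

    Attributes
    ----------
    variance_order_ : ndarray
        Variable indices by descending variance.
    subsets_ : SubsetSeries
    runs_ : GridRuns
    tensor_ : ValidityTensor
    tiny_cluster_profile_ : selection.TinyClusterProfile
    monotonicity_profile_ : selection.MonotonicityProfile
    retained_algorithms_, retained_metrics_, final_metrics_ : list of str
    map_ : ZMeasureMap
    red_points_, blue_points_ : list
        Per-subset marked optima (steepest interior peak / argmax K).
    """

    def __init__(
        self,
        k_range=(2, 10),
        subset_sizes=None,
        subset_step=None,
        algorithms=ALGORITHMS,
        n_metric_groups=4,
        min_cluster_size=3,
        gap_b=50,
        include_gap=True,
        random_state=0,
    ):
        self.k_range = k_range
        self.subset_sizes = subset_sizes
        self.subset_step = subset_step
        self.algorithms = algorithms
        self.n_metric_groups = n_metric_groups
        self.min_cluster_size = min_cluster_size
        self.gap_b = gap_b
        self.include_gap = include_gap
        self.random_state = random_state

    def _resolve_sizes(self, p: int) -> list[int]:
        if self.subset_sizes is not None and self.subset_step is not None:
            raise ValueError("give subset_sizes or subset_step, not both")
        if self.subset_sizes is not None:
            return list(self.subset_sizes)
        if self.subset_step is not None:
            from .data_io import step_sizes

            return step_sizes(p, int(self.subset_step))
        sizes = sorted({max(1, round(p * f)) for f in (0.2, 0.4, 0.6, 0.8, 1.0)})
        return sizes

    def fit(self, X, y=None):
        m = _as_expression_matrix(X)
        self.variance_order_ = rank_by_variance(m)
        self.subsets_ = make_subsets(m, self._resolve_sizes(m.n_variables))
        seed = int(self.random_state or 0)
        self.runs_ = run_grid(
            m, self.subsets_, list(self.algorithms), tuple(self.k_range), seed
        )
        self.tensor_ = score_grid(
            m=m,
            runs=self.runs_,
            subsets=self.subsets_,
            gap_b=self.gap_b,
            seed=seed,
            include_gap=self.include_gap,
        )
        self.tiny_cluster_profile_ = selection.filter_algorithms(
            self.runs_, self.min_cluster_size
        )
        self.monotonicity_profile_ = selection.filter_metrics(self.tensor_)
        self.retained_algorithms_ = self.tiny_cluster_profile_.retained
        self.retained_metrics_ = self.monotonicity_profile_.retained
        self.final_metrics_ = selection.select_final_metrics(
            self.tensor_,
            self.retained_metrics_,
            min(self.n_metric_groups, len(self.retained_metrics_)),
        )
        self.map_ = build_map(self.tensor_, self.final_metrics_, self.retained_algorithms_)
        self.red_points_ = self.map_.red_points
        self.blue_points_ = self.map_.blue_points
        self.n_features_in_ = m.n_variables
        return self

    def suggest_k(self) -> int:
        """The most frequently red-marked K across subsets (ties: smaller K)."""
        check_is_fitted(self, "map_")
        reds = [r for r in self.red_points_ if r is not None]
        if not reds:
            raise ValueError("no red points marked")
        vals, counts = np.unique(reds, return_counts=True)
        return int(vals[np.argmax(counts)])


class CoreClusterer(ClusterMixin, BaseEstimator):
    """Consensus clustering at a chosen (K, variable subset).

    Each algorithm in the roster clusters the top ``n_variables``
    highest-variance variables into ``k`` groups; labels are re-keyed to
    the reference algorithm's vocabulary via unanimous sample blocks,
    and each sample receives its modal label when at least ``threshold``
    of the algorithms agree (otherwise 0 = unassigned).

    Attributes
    ----------
    labels_ : ndarray of int
        Consensus labels in 0..k (0 = unassigned).
    assignment_matrix_ : ndarray
        Re-keyed samples x algorithms label matrix.
    blocks_ : list of Block
        Unanimous sample blocks, largest first.
    """

    def __init__(
        self,
        k=2,
        algorithms=ALGORITHMS,
        n_variables=None,
        threshold=0.5,
        reference=0,
        random_state=0,
    ):
        self.k = k
        self.algorithms = algorithms
        self.n_variables = n_variables
        self.threshold = threshold
        self.reference = reference
        self.random_state = random_state

    def fit(self, X, y=None):
        m = _as_expression_matrix(X)
        algorithms = list(self.algorithms)
        if not algorithms:
            raise ValueError("algorithm roster must not be empty")
        if self.n_variables is not None:
            order = rank_by_variance(m)
            data = m.values[:, order[: int(self.n_variables)]]
        else:
            data = m.values
        seed = int(self.random_state or 0)
        cols = [
            run_algorithm(data, alg, int(self.k), seed).labels for alg in algorithms
        ]
        raw = np.column_stack(cols)
        if raw.shape[1] >= 2:
            rekeyed = rekey(raw, int(self.k), reference=int(self.reference))
        else:
            rekeyed = raw
        core = core_clusters(rekeyed, float(self.threshold))
        self.assignment_matrix_ = rekeyed
        self.blocks_ = find_blocks(rekeyed) if raw.shape[1] >= 2 else []
        self.labels_ = core.labels
        self.n_features_in_ = m.n_variables
        return self
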