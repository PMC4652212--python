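"""Gaussian-mixture benchmark data and the simulation evaluation harness.

The generator emulates the simulated study design the method was
developed against: 300 samples drawn from K spherical Gaussian
components (K in {3, 5, 7}) in 1000 informative dimensions, optionally
padded with 1000 pure-noise N(0,1) variables.  Component means are
placed uniformly in the unit hypercube and the common within-component
standard deviation is calibrated so the mean pairwise overlap (the
probability of misclassifying a draw from one component as its
neighbour under the generating model) hits a target value, which
controls clustering difficulty.

The harness runs the full pipeline on such cases and tallies, per
validity metric, the accuracy (an oriented peak at the true K) and
monotonicity of its K-sequences, the tiny-cluster propensity of each
algorithm, and whether the map's red point recovers the true K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist
from scipy.stats import norm

from . import selection
from .cluster_algos import ALGORITHMS, run_grid
from .commap import ZMeasureMap, build_map
from .data_io import ExpressionMatrix, make_subsets, step_sizes
from .validity import HIGHER_BETTER, METRICS, ValidityTensor, score_grid

logger = logging.getLogger(__name__)

# Default mean pairwise misclassification probability between components.
# At the benchmark scale (p = 1000 informative dimensions, spherical
# components) cluster structure is empirically detectable only when the
# centre separation d satisfies d/sigma >~ sqrt(2) * p**0.25 ~ 8, i.e.
# overlap <~ 1e-4.  The default (d/sigma ~ 11) is the weakest separation,
# in decade steps, at which all six benchmark cases remain identifiable:
# K = 3 is cleanly recoverable while K = 7 stays borderline (its subsets
# are only partly correct and its peaks are the flattest).
DEFAULT_OVERLAP = 1e-8


@dataclass
class SimSpec:
    """Design of one simulated case."""

    n_samples: int = 300
    k_true: int = 3
    p_inform: int = 1000
    p_noise: int = 0
    overlap: float = DEFAULT_OVERLAP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if not (0.0 < self.overlap < 0.4):
            raise ValueError("overlap must lie in (0, 0.4)")
        if self.n_samples < 2 * self.k_true:
            raise ValueError("need at least 2 samples per component")

    @property
    def name(self) -> str:
        noise = f"noise{self.p_noise}" if self.p_noise else "no_noise"
        return f"K{self.k_true}_{noise}"


def _calibrate_sigma(mean_dists: np.ndarray, overlap: float) -> float:
    """Within-component sd such that mean pairwise misclassification = overlap.

    For two equal-weight spherical Gaussians at centre distance d the
    total pairwise misclassification probability is 2 * Phi(-d / (2 sigma)),
    so the mean over component pairs is monotone in sigma and is solved
    by bracketed root finding.
    """

    def mean_overlap(sigma: float) -> float:
        return float(np.mean(2.0 * norm.cdf(-mean_dists / (2.0 * sigma))))

    lo, hi = 1e-9, 1.0
    while mean_overlap(hi) < overlap:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError(
                "overlap calibration failed to bracket; increase separation bounds"
            )
    return float(brentq(lambda s: mean_overlap(s) - overlap, lo, hi, xtol=1e-12))


def simulate(spec: SimSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one simulated dataset; returns (matrix, true labels in 1..k)."""
    rng = np.random.default_rng(spec.seed)
    k, p, n = spec.k_true, spec.p_inform, spec.n_samples
    means = rng.uniform(0.0, 1.0, size=(k, p))
    sigma = _calibrate_sigma(pdist(means), spec.overlap)
    base, rem = divmod(n, k)
    sizes = np.array([base + (1 if c < rem else 0) for c in range(k)])
    labels = np.repeat(np.arange(1, k + 1), sizes)
    X = means[labels - 1] + sigma * rng.standard_normal((n, p))
    var_ids = [f"inf_{j + 1}" for j in range(p)]
    if spec.p_noise:
        X = np.hstack([X, rng.standard_normal((n, spec.p_noise))])
        var_ids += [f"noise_{j + 1}" for j in range(spec.p_noise)]
    perm = rng.permutation(n)
    m = ExpressionMatrix(
        values=X[perm],
        sample_ids=[f"S{i + 1}" for i in range(n)],
        variable_ids=var_ids,
    )
    return m, labels[perm]


def realized_overlap(spec: SimSpec) -> float:
    """Mean pairwise misclassification probability of the generated layout."""
    rng = np.random.default_rng(spec.seed)
    means = rng.uniform(0.0, 1.0, size=(spec.k_true, spec.p_inform))
    d = pdist(means)
    sigma = _calibrate_sigma(d, spec.overlap)
    return float(np.mean(2.0 * norm.cdf(-d / (2.0 * sigma))))


def default_specs(
    seed: int = 0,
    overlap: float = DEFAULT_OVERLAP,
    n_samples: int = 300,
    p_inform: int = 1000,
    p_noise: int = 1000,
) -> list[SimSpec]:
    """The six benchmark cases: K in {3,5,7} with and without noise variables."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(6) % (2**31)]
    specs = []
    i = 0
    for k in (3, 5, 7):
        for noise in (0, p_noise):
            specs.append(
                SimSpec(
                    n_samples=n_samples,
                    k_true=k,
                    p_inform=p_inform,
                    p_noise=noise,
                    overlap=overlap,
                    seed=child_seeds[i],
                )
            )
            i += 1
    return specs


def oriented_peak_at(
    values: np.ndarray, k_values: list[int], k_target: int, metric: str
) -> bool:
    """True when the metric's K-sequence has an oriented local maximum at k_target.

    Lower-better metrics are negated first.  An interior point is a peak
    when neither neighbour is higher and at least one is strictly lower;
    an edge point only when strictly better than its single neighbour.
    """
    v = np.asarray(values, dtype=float)
    if metric not in HIGHER_BETTER:
        v = -v
    i = k_values.index(k_target)
    if not np.isfinite(v[i]):
        return False
    if i == 0:
        return np.isfinite(v[1]) and v[0] > v[1]
    if i == len(v) - 1:
        return np.isfinite(v[i - 1]) and v[i] > v[i - 1]
    left, right = v[i - 1], v[i + 1]
    if not (np.isfinite(left) and np.isfinite(right)):
        return False
    return v[i] >= left and v[i] >= right and (v[i] > left or v[i] > right)


def metric_accuracy_percents(
    t: ValidityTensor, k_true: int
) -> dict[str, float]:
    """Percent of (algorithm, subset) K-sequences with a peak at the true K."""
    out: dict[str, float] = {}
    for mi, met in enumerate(t.metrics):
        flags = []
        for ai in range(len(t.algorithms)):
            for si in range(len(t.subset_sizes)):
                seq = t.values[mi, ai, :, si]
                if np.isfinite(seq).sum() < 2:
                    continue
                flags.append(oriented_peak_at(seq, t.k_values, k_true, met))
        out[met] = 100.0 * float(np.mean(flags)) if flags else np.nan
    return out


@dataclass
class CaseResult:
    """Everything recorded for one simulated case."""

    spec: SimSpec
    subset_sizes: list[int]
    tiny_percents: dict[str, float]
    metric_accuracy: dict[str, float]
    metric_monotonic: dict[str, float]
    retained_algorithms: list[str]
    retained_metrics: list[str]
    final_metrics: list[str]
    zmap: ZMeasureMap
    correct: list[bool]

    @property
    def percent_correct(self) -> float:
        return 100.0 * float(np.mean(self.correct))


@dataclass
class BenchmarkResult:
    """Aggregate tallies over the simulated cases."""

    cases: list[CaseResult]
    metrics: list[str] = field(default_factory=lambda: list(METRICS))

    def metric_means(self, which: str) -> dict[str, float]:
        """Per-metric mean percent over cases; which in {'accuracy','monotonic'}."""
        attr = "metric_accuracy" if which == "accuracy" else "metric_monotonic"
        return {
            met: float(np.nanmean([getattr(c, attr)[met] for c in self.cases]))
            for met in self.metrics
        }

    def overall_correct_percent(self) -> float:
        flags = [f for c in self.cases for f in c.correct]
        return 100.0 * float(np.mean(flags))

    def correct_percent_for_k(self, k_true: int) -> float:
        flags = [
            f for c in self.cases if c.spec.k_true == k_true for f in c.correct
        ]
        if not flags:
            return float("nan")
        return 100.0 * float(np.mean(flags))

    def all_cases_identified(self) -> bool:
        """True when every case's map marks the true K in at least one subset
        and the true K is the most frequently marked K of that case."""
        for c in self.cases:
            reds = [r for r in c.zmap.red_points if r is not None]
            if not reds:
                return False
            vals, counts = np.unique(reds, return_counts=True)
            modal = vals[counts == counts.max()]
            if c.spec.k_true not in modal:
                return False
        return True

    def summary(self) -> dict[str, float | str]:
        acc = self.metric_means("accuracy")
        mono = self.metric_means("monotonic")
        best_metric = max(acc, key=lambda m: (acc[m], m))
        a = np.array([acc[m] for m in self.metrics])
        b = np.array([mono[m] for m in self.metrics])
        r = float(np.corrcoef(b, a)[0, 1])
        return {
            "overall_correct_pct": self.overall_correct_percent(),
            "k7_correct_pct": self.correct_percent_for_k(7),
            "best_metric": best_metric,
            "best_metric_accuracy_pct": float(acc[best_metric]),
            "monotonic_accuracy_corr": r,
            "median_monotonic_pct": float(np.median(b)),
            "gap_monotonic_pct": float(mono["gap"]),
            "gap_accuracy_pct": float(acc["gap"]),
            "n_case_subsets": sum(len(c.correct) for c in self.cases),
        }


def run_case(
    spec: SimSpec,
    *,
    k_range: tuple[int, int] = (2, 10),
    subset_step: int = 200,
    algorithms: tuple[str, ...] = ALGORITHMS,
    gap_b: int = 20,
    n_groups: int = 5,
    min_size: int = selection.DEFAULT_MIN_SIZE,
    seed: int | None = None,
) -> CaseResult:
    """Simulate one case and run the full pipeline on it."""
    seed = spec.seed if seed is None else seed
    m, _truth = simulate(spec)
    subsets = make_subsets(m, step_sizes(m.n_variables, subset_step))
    runs = run_grid(m, subsets, algorithms, k_range, seed)
    tensor = score_grid(runs, m, subsets, gap_b=gap_b, seed=seed)
    tiny = selection.filter_algorithms(runs, min_size)
    mono = selection.filter_metrics(tensor)
    final = selection.select_final_metrics(
        tensor, mono.retained, min(n_groups, len(mono.retained))
    )
    zmap = build_map(tensor, final, tiny.retained)
    correct = [r == spec.k_true for r in zmap.red_points]
    logger.info(
        "case %s: red points %s (true K=%d)", spec.name, zmap.red_points, spec.k_true
    )
    return CaseResult(
        spec=spec,
        subset_sizes=list(subsets.sizes),
        tiny_percents=tiny.percents,
        metric_accuracy=metric_accuracy_percents(tensor, spec.k_true),
        metric_monotonic=selection.monotonic_percents(tensor),
        retained_algorithms=tiny.retained,
        retained_metrics=mono.retained,
        final_metrics=final,
        zmap=zmap,
        correct=correct,
    )


def run_benchmark(specs: list[SimSpec], **case_kwargs) -> BenchmarkResult:
    """Run the full pipeline on every case and aggregate the tallies."""
    if not specs:
        raise ValueError("at least one SimSpec is required")
    cases = [run_case(spec, **case_kwargs) for spec in specs]
    return BenchmarkResult(cases=cases)


def accuracy_table(result: BenchmarkResult) -> str:
    """TSV with per-metric mean/sd accuracy and monotonicity over cases."""
    lines = ["metric\taccuracy_mean\taccuracy_sd\tmonotonic_mean\tmonotonic_sd"]
    for met in result.metrics:
        acc = np.array([c.metric_accuracy[met] for c in result.cases])
        mono = np.array([c.metric_monotonic[met] for c in result.cases])
        lines.append(
            f"{met}\t{np.nanmean(acc):.1f}\t{np.nanstd(acc, ddof=1):.1f}"
            f"\t{np.nanmean(mono):.1f}\t{np.nanstd(mono, ddof=1):.1f}"
        )
    return "\n".join(lines) + "\n"


def tiny_cluster_table(result: BenchmarkResult) -> str:
    """TSV with per-case, per-algorithm tiny-cluster percentages."""
    algos = list(result.cases[0].tiny_percents)
    lines = ["case\t" + "\t".join(algos)]
    for c in result.cases:
        lines.append(
            c.spec.name + "\t" + "\t".join(f"{c.tiny_percents[a]:.1f}" for a in algos)
        )
    return "\n".join(lines) + "\n"
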