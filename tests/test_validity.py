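"""Validity indices checked against an independent brute-force oracle.

The oracle enumerates pairs (and pair-of-pairs for G2) directly from
coordinates with plain Python loops, sharing no code with the
implementation under test.
"""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from communal.cluster_algos import run_algorithm
from communal.data_io import ExpressionMatrix, make_subsets
from communal.validity import (
    METRICS,
    ORIENTATION,
    PAIRWISE_METRICS,
    gap_statistic,
    score_grid,
    score_run,
)
from communal.cluster_algos import run_grid

# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _kruskal_max_edge(D, members):
    """Largest MST edge of the complete graph on `members` (Kruskal)."""
    if len(members) < 2:
        return 0.0
    edges = sorted(
        (D[a, b], a, b) for i, a in enumerate(members) for b in members[i + 1 :]
    )
    parent = {m: m for m in members}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    used, best = 0, 0.0
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            best = max(best, w)
            used += 1
            if used == len(members) - 1:
                break
    return best


def brute_force_scores(X, labels):
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = len(labels)
    D = squareform(pdist(X))
    clusters = sorted(set(labels))
    members = {c: [i for i in range(n) if labels[i] == c] for c in clusters}
    out = {m: math.nan for m in PAIRWISE_METRICS}
    if len(clusters) < 2:
        return out

    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(D[i, j])

    if within:
        out["avg_within"] = sum(within) / len(within)
    if between:
        out["avg_between"] = sum(between) / len(between)
    if within and between and out["avg_between"] > 0:
        out["wb_ratio"] = out["avg_within"] / out["avg_between"]

    # silhouette
    svals = []
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            svals.append(0.0)
            continue
        a = sum(D[i, j] for j in own if j != i) / (len(own) - 1)
        b = min(
            sum(D[i, j] for j in members[c]) / len(members[c])
            for c in clusters
            if c != labels[i]
        )
        svals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    out["avg_silwidth"] = sum(svals) / n

    # centroid-based sums of squares (independent of the distance identity)
    overall = X.mean(axis=0)
    W = sum(
        ((X[members[c]] - X[members[c]].mean(axis=0)) ** 2).sum() for c in clusters
    )
    B = sum(
        len(members[c]) * ((X[members[c]].mean(axis=0) - overall) ** 2).sum()
        for c in clusters
    )
    out["wcss"] = W
    m = len(clusters)
    if n > m and W > 0:
        out["ch_index"] = (B / (m - 1)) / (W / (n - m))

    out["entropy"] = -sum(
        (len(members[c]) / n) * math.log(len(members[c]) / n) for c in clusters
    )

    out["max_diameter"] = max(
        (D[a, b] for c in clusters for a in members[c] for b in members[c] if a < b),
        default=0.0,
    )
    out["min_separation"] = min(
        D[a, b]
        for c in clusters
        for d in clusters
        if c < d
        for a in members[c]
        for b in members[d]
    )
    if out["max_diameter"] > 0:
        out["dunn"] = out["min_separation"] / out["max_diameter"]

    between_means = [
        np.mean([D[a, b] for a in members[c] for b in members[d]])
        for c in clusters
        for d in clusters
        if c != d
    ]
    within_means = [
        np.mean([D[a, b] for a in members[c] for b in members[c] if a < b])
        for c in clusters
        if len(members[c]) > 1
    ]
    if within_means and max(within_means) > 0:
        out["dunn2"] = min(between_means) / max(within_means)

    # connectivity with L = min(10, n-1), ties broken by index
    L = min(10, n - 1)
    conn = 0.0
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (D[i, j], j))
        for rank, j in enumerate(order[:L], start=1):
            if labels[j] != labels[i]:
                conn += 1.0 / rank
    out["connectivity"] = conn

    # G2: concordant/discordant (within, between) pairs; ties count neither
    if within and between:
        s_plus = sum(1 for w in within for b in between if w < b)
        s_minus = sum(1 for w in within for b in between if w > b)
        if s_plus + s_minus:
            out["g2"] = (s_plus - s_minus) / (s_plus + s_minus)

    # G3
    alld = sorted(within + between)
    mw = len(within)
    if 0 < mw < len(alld):
        s_min = sum(alld[:mw])
        s_max = sum(alld[-mw:])
        if s_max > s_min:
            out["g3"] = (sum(within) - s_min) / (s_max - s_min)

    # Pearson gamma
    dvec, ivec = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dvec.append(D[i, j])
            ivec.append(0.0 if labels[i] == labels[j] else 1.0)
    if np.std(dvec) > 0 and np.std(ivec) > 0:
        out["pearson_gamma"] = float(np.corrcoef(dvec, ivec)[0, 1])

    # separation index
    nearest_other = [
        min(D[i, j] for j in range(n) if labels[j] != labels[i]) for i in range(n)
    ]
    nsep = max(1, round(0.1 * n))
    out["sep_index"] = sum(sorted(nearest_other)[:nsep]) / nsep

    out["widest_gap"] = max(_kruskal_max_edge(D, members[c]) for c in clusters)
    return out


def set_partitions(items):
    """All set partitions (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _assert_matches(fast, brute):
    for met in PAIRWISE_METRICS:
        f, b = fast[met], brute[met]
        if math.isnan(b):
            assert math.isnan(f), f"{met}: expected NaN, got {f}"
        else:
            assert f == pytest.approx(b, rel=1e-8, abs=1e-10), met


class TestBruteForceEquivalence:
    def test_all_partitions_of_eight_points(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(8, 3))
        from communal.validity import DistanceCache, _score_cached

        cache = DistanceCache(X)
        n_checked = 0
        for part in set_partitions(list(range(8))):
            if not (2 <= len(part) <= 7):
                continue
            labels = np.empty(8, dtype=int)
            for ci, block in enumerate(part, start=1):
                labels[block] = ci
            _assert_matches(_score_cached(cache, labels), brute_force_scores(X, labels))
            n_checked += 1
        assert n_checked == 4140 - 2  # all partitions except m=1 and m=8

    def test_random_labelings_twenty_points(self, rng):
        X = rng.normal(size=(20, 4))
        for _ in range(10):
            k = int(rng.integers(2, 7))
            labels = rng.integers(1, k + 1, size=20)
            if len(np.unique(labels)) < 2:
                continue
            _assert_matches(score_run(X, labels, k), brute_force_scores(X, labels))


class TestMetricProperties:
    def test_label_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        labels = rng.integers(1, 5, size=30)
        base = score_run(X, labels, 4)
        for _ in range(5):
            perm = rng.permutation(4) + 1
            scores = score_run(X, perm[labels - 1], 4)
            for met in PAIRWISE_METRICS:
                np.testing.assert_allclose(scores[met], base[met], rtol=1e-10)

    def test_scaling_behaviour(self, rng):
        X = rng.normal(size=(25, 3))
        labels = rng.integers(1, 4, size=25)
        base = score_run(X, labels, 3)
        c = 3.7
        scaled = score_run(c * X, labels, 3)
        linear = [
            "avg_between",
            "avg_within",
            "max_diameter",
            "min_separation",
            "widest_gap",
            "sep_index",
        ]
        invariant = [
            "avg_silwidth",
            "dunn",
            "dunn2",
            "g2",
            "g3",
            "pearson_gamma",
            "entropy",
            "wb_ratio",
            "ch_index",
            "connectivity",
        ]
        for met in linear:
            assert scaled[met] == pytest.approx(c * base[met], rel=1e-10)
        assert scaled["wcss"] == pytest.approx(c**2 * base["wcss"], rel=1e-10)
        for met in invariant:
            assert scaled[met] == pytest.approx(base[met], rel=1e-9)

    def test_equal_cluster_sizes_maximise_entropy(self, rng):
        X = rng.normal(size=(24, 2))
        labels = np.repeat([1, 2, 3], 8)
        assert score_run(X, labels, 3)["entropy"] == pytest.approx(math.log(3))

    def test_dunn_identity(self, rng):
        X = rng.normal(size=(20, 2))
        labels = rng.integers(1, 4, size=20)
        s = score_run(X, labels, 3)
        assert s["dunn"] == pytest.approx(s["min_separation"] / s["max_diameter"])

    def test_orientation_table_complete(self):
        assert set(ORIENTATION) == set(METRICS)
        assert ORIENTATION["dunn"] == "higher_better"
        assert ORIENTATION["wcss"] == "lower_better"


class TestGapStatistic:
    @staticmethod
    def _kmeans_fn(data, k):
        return run_algorithm(data, "kmeans", k, seed=0).labels if k > 1 else np.ones(
            len(data), dtype=int
        )

    def test_two_separated_gaussians_prefer_k2(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, (30, 2)), rng.normal(20, 1, (30, 2))]
        )
        g1 = gap_statistic(X, self._kmeans_fn, 1, B=20, seed=3)
        g2 = gap_statistic(X, self._kmeans_fn, 2, B=20, seed=3)
        assert g2.gap > g1.gap
        assert g2.se >= 0

    def test_curve_peaks_at_three_clusters(self, three_blob_data):
        X, _ = three_blob_data
        gaps = [
            gap_statistic(X, self._kmeans_fn, k, B=50, seed=5).gap for k in range(1, 7)
        ]
        assert int(np.argmax(gaps)) + 1 == 3

    def test_degenerate_data_errors(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError):
            gap_statistic(X, self._kmeans_fn, 2, B=5, seed=0)


class TestScoreGrid:
    def test_tensor_shape_and_consistency(self, rng):
        vals = rng.normal(size=(20, 10))
        m = ExpressionMatrix(
            values=vals,
            sample_ids=[f"s{i}" for i in range(20)],
            variable_ids=[f"g{j}" for j in range(10)],
        )
        subsets = make_subsets(m, [5, 10])
        runs = run_grid(m, subsets, ["kmeans", "pam"], (2, 4), seed=0)
        t = score_grid(runs, m, subsets, gap_b=3, seed=0)
        assert t.values.shape == (len(METRICS), 2, 3, 2)
        # cells agree with direct scoring on the same subset
        run = runs.get("pam", 5, 3)
        direct = score_run(vals[:, subsets.indices(0)], run.labels, 3)
        for met in PAIRWISE_METRICS:
            got = t.get(met, "pam", 3, 5)
            if math.isnan(direct[met]):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(direct[met], rel=1e-12)

    def test_absent_run_yields_absent_cells(self, rng):
        vals = rng.normal(size=(15, 6))
        m = ExpressionMatrix(
            values=vals,
            sample_ids=[f"s{i}" for i in range(15)],
            variable_ids=[f"g{j}" for j in range(6)],
        )
        subsets = make_subsets(m, [6])
        runs = run_grid(m, subsets, ["kmeans"], (2, 3), seed=0)
        del runs.runs[("kmeans", 6, 3)]
        t = score_grid(runs, m, subsets, include_gap=False)
        assert np.all(np.isnan(t.values[:, 0, 1, 0]))
        assert np.all(np.isfinite(t.values[t.metrics.index("dunn"), 0, 0, 0]))
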