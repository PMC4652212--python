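import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from communal.cluster_algos import ClusterRun, GridRuns
from communal.selection import (
    filter_algorithms,
    filter_metrics,
    is_monotone,
    monotonic_percents,
    select_final_metrics,
    tiny_cluster_percents,
)
from communal.validity import ValidityTensor


def _make_runs(tiny_fraction_by_algo, n_runs=4, n=30):
    """GridRuns where each algorithm has a controlled fraction of tiny-cluster runs."""
    runs = {}
    algos = list(tiny_fraction_by_algo)
    for alg, frac in tiny_fraction_by_algo.items():
        n_tiny = round(frac * n_runs)
        for r in range(n_runs):
            labels = np.ones(n, dtype=int)
            labels[n // 2 :] = 2
            if r < n_tiny:
                labels[:2] = 1
                labels[2 : n // 2] = 3
                k = 3
            else:
                k = 2
            runs[(alg, 10 + r, k)] = ClusterRun(
                algorithm=alg, subset_size=10 + r, k=k, labels=labels
            )
    sizes = sorted({s for (_, s, _) in runs})
    kv = sorted({k for (_, _, k) in runs})
    return GridRuns(runs=runs, algorithms=algos, subset_sizes=sizes, k_values=kv)


class TestAlgorithmFilter:
    def test_strictly_above_mean_removed(self):
        # fractions 0, .25, .5 -> percents 0, 25, 50; mean 25 -> only 50 removed
        runs = _make_runs({"a": 0.0, "b": 0.25, "c": 0.5})
        prof = filter_algorithms(runs)
        assert prof.retained == ["a", "b"]
        assert prof.percents["c"] == pytest.approx(50.0)

    def test_all_clean_none_removed(self):
        runs = _make_runs({"a": 0.0, "b": 0.0, "c": 0.0})
        assert filter_algorithms(runs).retained == ["a", "b", "c"]

    def test_single_dirty_algorithm_removed(self):
        runs = _make_runs({"a": 0.0, "b": 0.0, "c": 0.25})
        assert filter_algorithms(runs).retained == ["a", "b"]

    def test_percents_independent_of_roster(self):
        # an algorithm's tiny-cluster percent depends only on its own runs
        runs = _make_runs({"a": 0.0, "b": 0.25, "c": 0.5})
        full = tiny_cluster_percents(runs)
        pruned = GridRuns(
            runs={key: r for key, r in runs.runs.items() if key[0] != "c"},
            algorithms=["a", "b"],
            subset_sizes=runs.subset_sizes,
            k_values=runs.k_values,
        )
        sub = tiny_cluster_percents(pruned)
        assert sub == {k: v for k, v in full.items() if k != "c"}

    def test_tiny_percent_counts_any_small_cluster(self):
        labels = np.ones(10, dtype=int)
        labels[:2] = 2  # one cluster of size 2 < 3
        runs = GridRuns(
            runs={
                ("a", 5, 2): ClusterRun("a", 5, 2, labels),
                ("b", 5, 2): ClusterRun("b", 5, 2, np.repeat([1, 2], 5)),
            },
            algorithms=["a", "b"],
            subset_sizes=[5],
            k_values=[2],
        )
        assert tiny_cluster_percents(runs) == {"a": 100.0, "b": 0.0}
        assert filter_algorithms(runs).retained == ["b"]


def _tensor(values_by_metric, k_values=(2, 3, 4, 5)):
    """ValidityTensor with one algorithm and one subset per metric sequence set."""
    metrics = list(values_by_metric)
    n_seq = len(next(iter(values_by_metric.values())))
    vals = np.full((len(metrics), n_seq, len(k_values), 1), np.nan)
    for mi, met in enumerate(metrics):
        for ai, seq in enumerate(values_by_metric[met]):
            vals[mi, ai, :, 0] = seq
    return ValidityTensor(
        values=vals,
        metrics=metrics,
        algorithms=[f"alg{i}" for i in range(n_seq)],
        k_values=list(k_values),
        subset_sizes=[100],
    )


class TestMetricFilter:
    def test_monotone_definitions(self):
        assert is_monotone([1, 2, 3, 4])
        assert is_monotone([4, 3, 3, 1])
        assert is_monotone([2, 2, 2, 2])  # constant counts as monotone
        assert not is_monotone([0, 5, 0, 1])
        with pytest.raises(ValueError):
            is_monotone([1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seq=st.lists(st.integers(-100, 100), min_size=3, max_size=9),
        a=st.floats(min_value=0.5, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_monotonicity_invariant_under_increasing_transform(self, seq, a, b):
        # strictly increasing transforms (affine, cubic) preserve monotonicity
        v = np.array(seq, dtype=float)
        assert is_monotone(v) == is_monotone(a * v + b)
        assert is_monotone(v) == is_monotone(v**3)

    def test_always_monotone_metric_removed_peaked_retained(self):
        t = _tensor(
            {
                "rising": [[1, 2, 3, 4], [2, 3, 4, 5]],
                "constant": [[1, 1, 1, 1], [7, 7, 7, 7]],
                "peaked": [[0, 5, 1, 0], [1, 9, 2, 1]],
                "half": [[1, 2, 3, 4], [0, 5, 1, 0]],
                "peaked2": [[0, 3, 1, 0], [0, 8, 1, 0]],
            }
        )
        prof = filter_metrics(t)
        # percents: 100, 100, 0, 50, 0 -> median 50; strictly above removed
        assert prof.percents["rising"] == 100.0
        assert prof.percents["peaked"] == 0.0
        assert set(prof.retained) == {"peaked", "peaked2", "half"}

    def test_metric_at_median_retained(self):
        t = _tensor(
            {
                "a": [[1, 2, 3, 4]],
                "b": [[0, 5, 1, 0]],
                "c": [[1, 2, 3, 4]],
            }
        )
        prof = filter_metrics(t)
        # percents 100, 0, 100 -> median 100: nothing strictly above
        assert set(prof.retained) == {"a", "b", "c"}


class TestFinalMetricSelection:
    def _corr_tensor(self, rng):
        # metric y == 2x + 3 (perfectly correlated), z independent
        n_cells = 40
        x = rng.normal(size=n_cells)
        z = rng.normal(size=n_cells)
        vals = np.stack([x, 2 * x + 3, z]).reshape(3, 1, n_cells, 1)
        return ValidityTensor(
            values=vals,
            metrics=["x", "y", "z"],
            algorithms=["a"],
            k_values=list(range(n_cells)),
            subset_sizes=[10],
        )

    def test_n_groups_equal_retained_is_identity(self, rng):
        t = self._corr_tensor(rng)
        assert select_final_metrics(t, ["x", "y", "z"], 3) == ["x", "y", "z"]

    def test_correlated_pair_collapses(self, rng):
        t = self._corr_tensor(rng)
        final = select_final_metrics(t, ["x", "y", "z"], 2)
        assert len(final) == 2
        assert "z" in final
        assert len({"x", "y"} & set(final)) == 1

    def test_too_many_groups_errors(self, rng):
        with pytest.raises(ValueError):
            select_final_metrics(self._corr_tensor(rng), ["x", "y"], 3)

    def test_single_metric_returned_unchanged(self, rng):
        with pytest.warns(UserWarning):
            assert select_final_metrics(self._corr_tensor(rng), ["x"], 1) == ["x"]
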