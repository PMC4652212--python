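"""Input handling: matrix loading, variance ranking and nested variable subsets.

The clustering pipeline consumes a numeric samples-by-variables matrix
(e.g. log2 gene expression with variables = genes).  Variables are ranked
by descending variance across samples and grouped into progressively
growing, *nested* subsets: the highest-variance variables are present in
every tested subset, so the subset axis of the stability map describes
what happens as lower-variance variables are added.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SubsetSeries",
    "load_matrix",
    "rank_by_variance",
    "make_subsets",
]


@dataclass
class ExpressionMatrix:
    """A validated numeric matrix with rows = samples, columns = variables."""

    values: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.variable_ids) != p:
            raise ValueError(
                f"{len(self.variable_ids)} variable ids for {p} matrix columns"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, variable {self.variable_ids[bad[1]]!r}"
            )
        for name, ids in (("sample", self.sample_ids), ("variable", self.variable_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValueError(f"duplicate {name} id {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


@dataclass
class SubsetSeries:
    """Nested variable subsets along a single variance ordering.

    ``sizes`` is the strictly increasing list of subset sizes (the "n" axis
    of the stability map); ``ordering`` is a permutation of variable indices
    sorted by descending variance.  Subset i consists of the first
    ``sizes[i]`` entries of ``ordering``, hence every subset is a prefix of
    the next.
    """

    sizes: list[int]
    ordering: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sizes = [int(s) for s in self.sizes]
        self.ordering = np.asarray(self.ordering, dtype=int)
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("subset sizes must be strictly increasing")
        if self.sizes and self.sizes[-1] > self.ordering.size:
            raise ValueError("largest subset exceeds number of variables")

    def indices(self, i: int) -> np.ndarray:
        """Variable indices (into the original matrix) of the i-th subset."""
        return self.ordering[: self.sizes[i]]

    def __len__(self) -> int:
        return len(self.sizes)


def load_matrix(
    path: str | os.PathLike,
    orientation: str = "samples_rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a CSV/TSV matrix (one header row, one leading ID column).

    Parameters
    ----------
    orientation : {"samples_rows", "samples_cols"}
        How the file is laid out.  ``samples_cols`` (variables as rows,
        the dominant dialect for gene-expression matrices) is transposed
        on load so the returned matrix is always samples x variables.
    delimiter : str, optional
        Field delimiter; inferred from the extension when omitted
        (``.csv`` -> comma, anything else -> tab).
    """
    if orientation not in ("samples_rows", "samples_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if delimiter is None:
        delimiter = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}; "
            "missing values are not imputed"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric cell at row {bad!r}, column {col!r}")
    if orientation == "samples_cols":
        df = df.T
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(i) for i in df.index],
        variable_ids=[str(c) for c in df.columns],
    )


def write_matrix(
    m: ExpressionMatrix, path: str | os.PathLike, delimiter: str | None = None
) -> None:
    """Write an ExpressionMatrix in samples-rows orientation (round-trips with load_matrix)."""
    if delimiter is None:
        delimiter = "," if str(path).lower().endswith(".csv") else "\t"
    pd.DataFrame(
        m.values, index=m.sample_ids, columns=m.variable_ids
    ).to_csv(path, sep=delimiter)


def rank_by_variance(m: ExpressionMatrix) -> np.ndarray:
    """Permutation of variable indices by descending sample variance.

    Variance is the unbiased (N-1) sample variance across samples.  Ties
    keep original column order (stable sort on the negated variances).
    """
    if m.n_samples < 2:
        raise ValueError("variance ranking requires at least 2 samples")
    var = m.values.var(axis=0, ddof=1)
    return np.argsort(-var, kind="stable")


def make_subsets(m: ExpressionMatrix, sizes: list[int] | np.ndarray) -> SubsetSeries:
    """Build the nested subset series for the given sizes.

    Sizes are sorted ascending and de-duplicated; each must be a positive
    integer no larger than the number of variables.
    """
    sizes = sorted({int(s) for s in np.asarray(sizes, dtype=int).ravel()})
    if not sizes:
        raise ValueError("at least one subset size is required")
    if sizes[0] < 1:
        raise ValueError("subset sizes must be positive")
    if sizes[-1] > m.n_variables:
        raise ValueError(
            f"subset size {sizes[-1]} exceeds the {m.n_variables} available variables"
        )
    return SubsetSeries(sizes=sizes, ordering=rank_by_variance(m))


def step_sizes(n_variables: int, step: int) -> list[int]:
    """Subset sizes step, 2*step, ... up to n_variables (included if not a multiple)."""
    if step < 1:
        raise ValueError("step must be positive")
    sizes = list(range(step, n_variables + 1, step))
    if not sizes or sizes[-1] != n_variables:
        sizes.append(n_variables)
    return sizes
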