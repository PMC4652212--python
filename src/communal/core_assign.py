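"""Consensus ("core") cluster assignments across algorithms.

Different algorithms give arbitrary names to the same clusters and may
disagree on individual samples.  Re-keying aligns the label vocabularies
using unanimous blocks of samples as anchors; a majority vote with a
user threshold then yields per-sample consensus labels, with 0 marking
samples on which too few algorithms agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RekeyError",
    "Block",
    "CoreAssignment",
    "find_blocks",
    "rekey",
    "core_clusters",
    "compare_lambda",
]

REKEY_ADVICE = (
    "re-keying failed: select fewer algorithms over which to integrate the "
    "signal (consensus from a single algorithm is always possible)"
)


class RekeyError(ValueError):
    """Raised when block-based label re-keying is under-determined or inconsistent."""


@dataclass
class Block:
    """Maximal group of samples with identical cross-algorithm label vectors."""

    samples: np.ndarray
    vector: tuple[int, ...]

    @property
    def size(self) -> int:
        return int(self.samples.size)


@dataclass
class CoreAssignment:
    """Per-sample consensus label (0 = unassigned) after re-keying."""

    labels: np.ndarray
    threshold: float
    blocks: list[Block] = field(default_factory=list)

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == 0).sum())


def _as_matrix(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=int)
    if a.ndim != 2:
        raise ValueError("assignment matrix must be samples x algorithms")
    return a


def find_blocks(a: np.ndarray) -> list[Block]:
    """Blocks of samples with identical label vectors, sorted by size descending.

    Ties in size break by first sample index (deterministic).
    """
    a = _as_matrix(a)
    if a.shape[1] < 2:
        raise ValueError("block search needs at least 2 algorithms")
    vectors: dict[tuple[int, ...], list[int]] = {}
    for i, row in enumerate(a):
        vectors.setdefault(tuple(int(x) for x in row), []).append(i)
    blocks = [
        Block(samples=np.array(idx), vector=vec) for vec, idx in vectors.items()
    ]
    blocks.sort(key=lambda b: (-b.size, int(b.samples[0])))
    return blocks


def rekey(a: np.ndarray, k: int, reference: int = 0) -> np.ndarray:
    """Re-key every algorithm's labels onto the reference algorithm's vocabulary.

    The k-1 largest blocks with distinct reference labels anchor a
    bijection per algorithm (source label -> reference label); the k-th
    correspondence follows by elimination.  Raises :class:`RekeyError`
    when fewer than k-1 usable blocks exist (the system is
    under-determined) or when one source label would map to two
    different reference labels (inconsistency, reported with the
    offending algorithm).
    """
    a = _as_matrix(a)
    n, n_alg = a.shape
    if not (0 <= reference < n_alg):
        raise ValueError(f"reference algorithm index {reference} out of range")
    blocks = find_blocks(a)
    anchors: list[Block] = []
    seen_ref: set[int] = set()
    for b in blocks:
        ref_label = b.vector[reference]
        if ref_label in seen_ref:
            continue
        anchors.append(b)
        seen_ref.add(ref_label)
        if len(anchors) == k - 1:
            break
    if len(anchors) < k - 1:
        raise RekeyError(
            f"only {len(anchors)} usable anchor blocks for k={k}; " + REKEY_ADVICE
        )
    all_labels = set(range(1, k + 1))
    out = a.copy()
    for j in range(n_alg):
        mapping: dict[int, int] = {}
        for b in anchors:
            src, ref = b.vector[j], b.vector[reference]
            if src in mapping and mapping[src] != ref:
                raise RekeyError(
                    f"inconsistent correspondences for algorithm column {j}: "
                    f"label {src} maps to both {mapping[src]} and {ref}; "
                    + REKEY_ADVICE
                )
            mapping[src] = ref
        if len(set(mapping.values())) != len(mapping):
            raise RekeyError(
                f"two labels of algorithm column {j} map to one reference label; "
                + REKEY_ADVICE
            )
        missing_src = sorted(all_labels - set(mapping))
        missing_ref = sorted(all_labels - set(mapping.values()))
        if len(missing_src) == 1 and len(missing_ref) == 1:
            mapping[missing_src[0]] = missing_ref[0]  # the k-th by elimination
        else:
            # labels absent from the data map identically among the leftovers
            for s, r in zip(missing_src, missing_ref):
                mapping[s] = r
        col = a[:, j]
        unseen = set(np.unique(col)) - set(mapping)
        if unseen:
            raise RekeyError(
                f"algorithm column {j} uses labels {sorted(unseen)} absent from "
                "all anchor blocks; " + REKEY_ADVICE
            )
        out[:, j] = np.vectorize(mapping.get)(col)
    return out


def core_clusters(a: np.ndarray, threshold: float = 0.5) -> CoreAssignment:
    """Majority vote per sample over re-keyed algorithm labels.

    A sample is assigned its modal label when the modal fraction reaches
    ``threshold``; otherwise (including modal ties) it gets 0.
    """
    a = _as_matrix(a)
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    n, n_alg = a.shape
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        vals, counts = np.unique(a[i], return_counts=True)
        top = counts.max()
        if top / n_alg >= threshold and (counts == top).sum() == 1:
            labels[i] = int(vals[np.argmax(counts)])
    return CoreAssignment(labels=labels, threshold=threshold, blocks=find_blocks(a) if n_alg >= 2 else [])


def compare_lambda(x: np.ndarray, y: np.ndarray) -> float:
    """Goodman-Kruskal lambda between two labelings, in [0, 1].

    The labeling with the fewer distinct clusters is the dependent
    variable (ties keep ``y`` dependent).  Samples labelled 0 (unassigned)
    in either labeling are excluded pairwise.  Raises when the dependent
    labeling has a single cluster (lambda undefined).
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("labelings must cover the same samples")
    keep = (x != 0) & (y != 0)
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("no jointly assigned samples")
    if len(np.unique(x)) < len(np.unique(y)):
        x, y = y, x  # ensure y (dependent) has the fewer clusters
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xv.size, yv.size), dtype=int)
    np.add.at(table, (xi, yi), 1)
    n = table.sum()
    max_col_total = table.sum(axis=0).max()
    if n == max_col_total:
        raise ValueError("dependent labeling has a single cluster; lambda undefined")
    return float((table.max(axis=1).sum() - max_col_total) / (n - max_col_total))
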