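"""The K x n stability map ("Z-measures") and its optimum markers.

For each selected validity metric and each retained algorithm, the K x n
matrix of raw index values is orientation-corrected (lower-better indices
are negated), z-scored jointly over all its cells, and averaged first
over algorithms and then over metrics.  The resulting map is annotated,
per subset column, with the steepest interior peak over K (red point,
most negative second difference) and the absolute maximum (blue point).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .validity import LOWER_BETTER, ValidityTensor


@dataclass
class ZMeasureMap:
    """z[k, subset] mean standardized oriented validity, with peak markers."""

    z: np.ndarray
    k_values: list[int]
    subset_sizes: list[int]
    metrics: list[str]
    algorithms: list[str]
    red_points: list[int | None] = field(default_factory=list)
    blue_points: list[int] = field(default_factory=list)

    def column(self, si: int) -> np.ndarray:
        return self.z[:, si]


def _zscore_slab(slab: np.ndarray) -> np.ndarray | None:
    """Z-score a K x n slab jointly over all finite cells (ddof=1)."""
    finite = np.isfinite(slab)
    if finite.sum() < 2:
        return None
    mu = slab[finite].mean()
    sd = slab[finite].std(ddof=1)
    if sd == 0:
        return None
    out = np.full_like(slab, np.nan)
    out[finite] = (slab[finite] - mu) / sd
    return out


def build_map(
    t: ValidityTensor,
    final_metrics: list[str],
    retained_algorithms: list[str],
) -> ZMeasureMap:
    """Aggregate selected metrics over retained algorithms into the map.

    Per metric: orient, z-score each algorithm's K x n slab over all its
    cells, average the slabs over algorithms; the map is the unweighted
    mean of the per-metric matrices.  A metric constant over all cells
    (zero variance) is dropped from the average with a warning.
    """
    if not final_metrics or not retained_algorithms:
        raise ValueError("need at least one metric and one algorithm")
    per_metric = []
    used_metrics = []
    for met in final_metrics:
        sign = -1.0 if met in LOWER_BETTER else 1.0
        slabs = []
        for alg in retained_algorithms:
            z = _zscore_slab(sign * t.slab(met, alg))
            if z is not None:
                slabs.append(z)
        if not slabs:
            warnings.warn(f"metric {met!r} constant over all cells; dropped from map")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_metric.append(np.nanmean(np.stack(slabs), axis=0))
        used_metrics.append(met)
    if not per_metric:
        raise ValueError("no usable metric slabs; cannot build map")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = np.nanmean(np.stack(per_metric), axis=0)
    m = ZMeasureMap(
        z=z,
        k_values=list(t.k_values),
        subset_sizes=list(t.subset_sizes),
        metrics=used_metrics,
        algorithms=list(retained_algorithms),
    )
    return mark_peaks(m)


def interior_maxima(v: np.ndarray) -> list[int]:
    """Indices of interior local maxima (>= both neighbours, one strictly).

    A flat plateau of equal maxima counts once, at its smallest index.
    """
    idx = []
    for i in range(1, len(v) - 1):
        if not np.isfinite(v[i]):
            continue
        if v[i] >= v[i - 1] and v[i] >= v[i + 1] and (v[i] > v[i - 1] or v[i] > v[i + 1]):
            # plateau: skip if the previous point is an equal accepted maximum
            if idx and v[idx[-1]] == v[i] and np.all(v[idx[-1] : i + 1] == v[i]):
                continue
            idx.append(i)
    return idx


def mark_peaks(m: ZMeasureMap) -> ZMeasureMap:
    """Annotate red (steepest interior peak) and blue (argmax) K per subset.

    The red point is the interior local maximum with the most negative
    second difference v[i+1] - 2 v[i] + v[i-1]; with no interior maximum
    it reverts to the edge K with the higher value.  Ties break toward
    smaller K.  Columns with fewer than 3 K values get no red point.
    """
    kv = m.k_values
    red: list[int | None] = []
    blue: list[int] = []
    for si in range(len(m.subset_sizes)):
        v = m.z[:, si]
        finite = np.isfinite(v)
        if not finite.any():
            red.append(None)
            blue.append(kv[0])
            continue
        vb = np.where(finite, v, -np.inf)
        blue.append(kv[int(np.argmax(vb))])
        if finite.sum() < 3 or len(kv) < 3:
            red.append(None)
            continue
        maxima = interior_maxima(v)
        if maxima:
            second = [v[i + 1] - 2 * v[i] + v[i - 1] for i in maxima]
            red.append(kv[maxima[int(np.argmin(second))]])
        else:
            lo, hi = v[0], v[-1]
            red.append(kv[0] if lo >= hi else kv[-1])
    m.red_points = red
    m.blue_points = blue
    return m


def export_map(
    m: ZMeasureMap,
    out_dir: str | os.PathLike,
    prefix: str = "communal_map",
    config: dict | None = None,
    surface_png: bool = False,
) -> dict[str, str]:
    """Write the map as TSV (K x n matrix) and JSON (matrix + annotations).

    Optionally renders a static 3D surface PNG.  Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    tsv_path = os.path.join(out_dir, f"{prefix}.tsv")
    with open(tsv_path, "w") as fh:
        fh.write("K\t" + "\t".join(str(s) for s in m.subset_sizes) + "\n")
        for ki, k in enumerate(m.k_values):
            row = "\t".join(f"{v:.10g}" if np.isfinite(v) else "NA" for v in m.z[ki])
            fh.write(f"{k}\t{row}\n")
    paths["tsv"] = tsv_path
    json_path = os.path.join(out_dir, f"{prefix}.json")
    payload = {
        "k_values": m.k_values,
        "subset_sizes": m.subset_sizes,
        "z": [[None if not np.isfinite(v) else float(v) for v in row] for row in m.z],
        "metrics": m.metrics,
        "algorithms": m.algorithms,
        "red_points": m.red_points,
        "blue_points": m.blue_points,
        "config": config or {},
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    paths["json"] = json_path
    if surface_png:
        paths["png"] = _surface_png(m, os.path.join(out_dir, f"{prefix}.png"))
    return paths


def load_map(json_path: str | os.PathLike) -> ZMeasureMap:
    """Reload a map exported by :func:`export_map` (JSON round-trip)."""
    with open(json_path) as fh:
        payload = json.load(fh)
    z = np.array(
        [[np.nan if v is None else v for v in row] for row in payload["z"]], dtype=float
    )
    return ZMeasureMap(
        z=z,
        k_values=[int(k) for k in payload["k_values"]],
        subset_sizes=[int(s) for s in payload["subset_sizes"]],
        metrics=list(payload["metrics"]),
        algorithms=list(payload["algorithms"]),
        red_points=[None if r is None else int(r) for r in payload["red_points"]],
        blue_points=[int(b) for b in payload["blue_points"]],
    )


def _surface_png(m: ZMeasureMap, path: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    K, S = np.meshgrid(m.k_values, np.arange(len(m.subset_sizes)), indexing="ij")
    Zs = np.where(np.isfinite(m.z), m.z, np.nanmin(m.z[np.isfinite(m.z)]))
    ax.plot_surface(K, S, Zs, cmap="viridis", alpha=0.85)
    for si, (r, b) in enumerate(zip(m.red_points, m.blue_points)):
        if r is not None:
            ax.scatter([r], [si], [m.z[m.k_values.index(r), si]], color="red", s=30)
        ax.scatter([b], [si], [m.z[m.k_values.index(b), si]], color="blue", s=20)
    ax.set_xlabel("K")
    ax.set_ylabel("variable subset")
    ax.set_zlabel("mean Z-measure")
    ax.set_yticks(np.arange(len(m.subset_sizes)))
    ax.set_yticklabels([str(s) for s in m.subset_sizes], fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
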