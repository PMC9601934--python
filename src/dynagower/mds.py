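"""Classical (principal-coordinates) MDS per time and the dynamic map series.

Each D(t) is double-centered (B = -1/2 J D J), eigendecomposed, and the
top-k positive-eigenvalue coordinates (scaled by the square root of the
eigenvalue) become that week's map.  Concatenating the per-time maps
gives the dynamic scatter series; optional chained orthogonal Procrustes
alignment removes the rotation/reflection ambiguity between consecutive
maps without altering any within-time distance.

The joint robust metric is not guaranteed Euclidean, so negative
eigenvalues can occur; they are dropped and their relative mass is
reported as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh, orthogonal_procrustes

from .distance import DistanceSeries, SquaredDistanceMatrix
from .panel import MixedPanel, PanelError, ValueTypeError

logger = logging.getLogger("dynagower")

__all__ = [
    "MDSConfiguration",
    "classical_mds",
    "align_series",
    "dynamic_mds_series",
    "marker_sizes",
    "coordinates_frame",
    "frames_bundle",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class MDSConfiguration:
    """Principal coordinates of one time slice.

    ``coordinates`` is ``n x k`` with columns ordered by descending
    eigenvalue and column-centered; ``explained_fraction`` divides each
    retained eigenvalue by the sum of all positive eigenvalues;
    ``negative_mass`` is the share |sum of negative eigenvalues| carries
    of the total absolute eigenvalue mass (non-Euclideanity diagnostic).
    """

    time: str
    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    negative_mass: float = 0.0


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: each column's largest-|.| entry >= 0."""
    coords = coords.copy()
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords


def classical_mds(D: SquaredDistanceMatrix, k: int) -> MDSConfiguration:
    """Principal-coordinates analysis of a squared-distance matrix.

    If D is exactly Euclidean-embeddable in k dimensions, the squared
    inter-point distances of the output reproduce D.  Fewer than k
    positive eigenvalues truncate the configuration with a warning; a
    zero matrix yields all-zero coordinates and zero eigenvalues.
    """
    n = D.n
    if n < 2:
        raise PanelError("classical MDS needs at least 2 points")
    if not 1 <= k <= n - 1:
        raise PanelError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * (J @ D.values @ J)
    B = (B + B.T) / 2.0
    w, U = eigh(B)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    scale = max(1.0, float(np.abs(w).max(initial=0.0)))
    positive = w > _EIG_TOL * scale
    negative = w < -_EIG_TOL * scale
    pos_sum = float(w[positive].sum())
    total_abs = float(np.abs(w[positive | negative]).sum())
    neg_mass = float(-w[negative].sum()) / total_abs if total_abs > 0 else 0.0

    n_pos = int(positive.sum())
    if n_pos == 0:
        return MDSConfiguration(
            D.component, D.labels, np.zeros((n, k)), np.zeros(k), np.zeros(k), neg_mass
        )
    kept = min(k, n_pos)
    if kept < k:
        logger.warning(
            "only %d positive eigenvalues available; k truncated from %d", n_pos, k
        )
    vals = w[:kept]
    coords = _fix_signs(U[:, :kept] * np.sqrt(vals))
    return MDSConfiguration(
        D.component, D.labels, coords, vals, vals / pos_sum, neg_mass
    )


def align_series(configs: list[MDSConfiguration]) -> list[MDSConfiguration]:
    """Chained orthogonal-Procrustes alignment of a configuration series.

    Each configuration is rotated/reflected (no scaling) to best match
    its aligned predecessor, removing arbitrary axis flips between
    consecutive maps; within-time inter-point distances are untouched.
    """
    if not configs:
        return []
    labels = configs[0].labels
    width = max(c.coordinates.shape[1] for c in configs)
    aligned = [replace(configs[0], coordinates=_pad(configs[0].coordinates, width))]
    for cfg in configs[1:]:
        if cfg.labels != labels:
            raise PanelError("all configurations must share the same entity labels")
        coords = _pad(cfg.coordinates, width)
        R, _ = orthogonal_procrustes(coords, aligned[-1].coordinates)
        aligned.append(replace(cfg, coordinates=coords @ R))
    return aligned


def _pad(coords: np.ndarray, width: int) -> np.ndarray:
    if coords.shape[1] == width:
        return coords
    out = np.zeros((coords.shape[0], width))
    out[:, : coords.shape[1]] = coords
    return out


def marker_sizes(
    panel: MixedPanel, size_by: str, times: list[str]
) -> dict[str, np.ndarray]:
    """Per-time marker sizes: the chosen variable min-max rescaled to [1, 5].

    A constant variable at some time maps every entity to 3, the midpoint
    of the range.
    """
    spec = panel.variable(size_by)
    if spec.vtype != "quantitative":
        raise ValueTypeError(
            f"size_by variable {size_by!r} must be quantitative, is {spec.vtype}"
        )
    sizes = {}
    for t in times:
        v = panel.slice_time(t)[size_by].to_numpy(dtype=float)
        rng = v.max() - v.min()
        sizes[t] = np.full_like(v, 3.0) if rng == 0 else 1.0 + 4.0 * (v - v.min()) / rng
    return sizes


def dynamic_mds_series(
    series: DistanceSeries,
    k: int = 2,
    size_by: str | None = None,
    panel: MixedPanel | None = None,
    align: bool = False,
) -> tuple[list[MDSConfiguration], dict[str, np.ndarray] | None]:
    """Per-time MDS maps (optionally Procrustes-aligned) plus marker sizes.

    ``size_by`` names a quantitative panel variable whose per-time values
    set the dot sizes in [1, 5]; it requires ``panel``.
    """
    configs = [classical_mds(m, k) for m in series.matrices]
    configs = [replace(c, time=t) for c, t in zip(configs, series.times)]
    if align:
        configs = align_series(configs)
    sizes = None
    if size_by is not None:
        if panel is None:
            raise PanelError("size_by requires the panel the series was built from")
        sizes = marker_sizes(panel, size_by, series.times)
    return configs, sizes


# ---------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------

def coordinates_frame(
    configs: list[MDSConfiguration], sizes: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Tidy per-time coordinates table (time, entity, pc1..pck[, size])."""
    rows = []
    for cfg in configs:
        k = cfg.coordinates.shape[1]
        for i, e in enumerate(cfg.labels):
            row = {"time": cfg.time, "entity": e}
            for c in range(k):
                row[f"pc{c + 1}"] = cfg.coordinates[i, c]
            if sizes is not None:
                row["size"] = float(sizes[cfg.time][i])
            rows.append(row)
    return pd.DataFrame(rows)


def frames_bundle(
    configs: list[MDSConfiguration], sizes: dict[str, np.ndarray] | None = None
) -> dict:
    """Animation-frame bundle (one frame per time) for any front end."""
    frames = []
    for cfg in configs:
        frame = {
            "time": cfg.time,
            "labels": list(cfg.labels),
            "coordinates": cfg.coordinates.tolist(),
            "eigenvalues": cfg.eigenvalues.tolist(),
            "explained_fraction": cfg.explained_fraction.tolist(),
            "negative_mass": cfg.negative_mass,
        }
        if sizes is not None:
            frame["sizes"] = sizes[cfg.time].tolist()
        frames.append(frame)
    return {"k": max((c.coordinates.shape[1] for c in configs), default=0), "frames": frames}
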