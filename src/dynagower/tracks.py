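"""Time-track analytics over a series of squared-distance matrices.

Given {D(t) : t in T} and its per-source raw components, this module
derives the line-graph material: per-source geometric-variability tracks,
pairwise-distance tracks, per-time extremes with the entity pairs
achieving them, the dynamic box plot (per-time five-number summary of all
pairwise distances), and the proximity function

    phi(z0(t)) = (1/n) * sum_i d2(z0(t), zi(t)) - VD(t),

whose large values flag entities systematically far from the sample.
Entities whose phi exceeds the per-time 90th percentile are marked as
potential outliers.

All quantiles and percentile thresholds use linear interpolation between
order statistics (numpy's default), making outputs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .distance import DistanceSeries
from .panel import PanelError

__all__ = [
    "VariabilityTrack",
    "ProximityTrack",
    "DegenerateTrackError",
    "variability_tracks",
    "rescale01",
    "pairwise_track",
    "extremes_track",
    "boxplot_series",
    "proximity_track",
    "proximity_of",
    "flag_outliers",
]


class DegenerateTrackError(PanelError):
    """A track is constant and cannot be rescaled to [0, 1]."""


@dataclass(frozen=True)
class VariabilityTrack:
    """Geometric variability VDk(t) of one data source over time."""

    source: str
    times: tuple[str, ...]
    values: np.ndarray
    rescaled: np.ndarray | None = None


@dataclass(frozen=True)
class ProximityTrack:
    """phi value per (entity, time), with optional outlier thresholds/flags.

    ``phi`` has shape ``(n, N)``.  ``thresholds`` holds the per-time
    percentile cut (or the single pooled cut broadcast over time) and
    ``flags`` marks entities strictly above it.
    """

    entities: tuple[str, ...]
    times: tuple[str, ...]
    phi: np.ndarray
    percentile: float | None = None
    thresholds: np.ndarray | None = None
    flags: np.ndarray | None = None
    include_self: bool = True

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame with columns time, entity, phi[, threshold, flagged]."""
        rows = []
        for j, t in enumerate(self.times):
            for i, e in enumerate(self.entities):
                row = {"time": t, "entity": e, "phi": self.phi[i, j]}
                if self.thresholds is not None:
                    row["threshold"] = self.thresholds[j]
                    row["flagged"] = bool(self.flags[i, j])
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# variability over time
# ---------------------------------------------------------------------

def variability_tracks(series: DistanceSeries) -> list[VariabilityTrack]:
    """One VDk(t) track per source, from the UN-normalized components.

    Normalized components have VD identically 1 by construction and carry
    no signal; the raw matrices are what reveal when a source's
    individuals spread apart or bunch together.
    """
    if not series.components_raw:
        raise PanelError(
            "series retains no per-source components; "
            "recompute with component tracking enabled"
        )
    tracks = []
    for key, mats in series.components_raw.items():
        values = np.array([m.gv for m in mats])
        tracks.append(VariabilityTrack(key, tuple(series.times), values))
    return tracks


def rescale01(track: VariabilityTrack) -> VariabilityTrack:
    """Min-max rescale a track to [0, 1] over its own time range.

    Used to compare sources whose raw variabilities live on different
    scales on one plot.  Idempotent; a constant track has no range and
    raises :class:`DegenerateTrackError`.
    """
    lo, hi = float(track.values.min()), float(track.values.max())
    if hi == lo:
        raise DegenerateTrackError(
            f"track {track.source!r} is constant; cannot rescale to [0, 1]"
        )
    return replace(track, rescaled=(track.values - lo) / (hi - lo))


def variability_frame(series: DistanceSeries) -> pd.DataFrame:
    """Tidy table (time, source, value, value01) for all sources."""
    rows = []
    for track in variability_tracks(series):
        try:
            track = rescale01(track)
            scaled = track.rescaled
        except DegenerateTrackError:
            scaled = np.full_like(track.values, np.nan)
        for t, v, s in zip(track.times, track.values, scaled):
            rows.append({"time": t, "source": track.source, "value": v, "value01": s})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# pairwise tracks and extremes
# ---------------------------------------------------------------------

def pairwise_track(series: DistanceSeries, i: str, j: str) -> np.ndarray:
    """Squared distance between entities ``i`` and ``j`` at each time."""
    if i == j:
        raise PanelError(f"pairwise track needs two distinct entities, got {i!r} twice")
    a = series.matrices[0].index(i)
    b = series.matrices[0].index(j)
    return np.array([m.values[a, b] for m in series.matrices])


def _condensed_pairs(labels: tuple[str, ...]) -> list[tuple[str, str]]:
    n = len(labels)
    return [(labels[a], labels[b]) for a in range(n) for b in range(a + 1, n)]


def extremes_track(series: DistanceSeries) -> pd.DataFrame:
    """Per-time min and max pairwise distances and the pairs achieving them.

    Ties are broken by the lexicographically smallest (entity_i, entity_j)
    pair; the condensed upper-triangle order is already lexicographic, so
    the first occurrence wins.
    """
    pairs = _condensed_pairs(series.labels)
    rows = []
    for t, m in zip(series.times, series.matrices):
        upper = m.upper_values()
        lo, hi = int(np.argmin(upper)), int(np.argmax(upper))
        rows.append(
            {
                "time": t,
                "min": upper[lo],
                "pair_min": "|".join(pairs[lo]),
                "max": upper[hi],
                "pair_max": "|".join(pairs[hi]),
            }
        )
    return pd.DataFrame(rows)


def boxplot_series(series: DistanceSeries) -> pd.DataFrame:
    """Dynamic box plot: five-number summary of pairwise distances per time.

    Quartiles use linear interpolation between order statistics over the
    n(n-1)/2 upper-triangle entries of D(t).
    """
    if series.n < 3:
        raise PanelError("dynamic box plot needs n >= 3 entities")
    rows = []
    for t, m in zip(series.times, series.matrices):
        upper = m.upper_values()
        lo, q1, med, q3, hi = np.percentile(upper, [0, 25, 50, 75, 100])
        rows.append(
            {"time": t, "min": lo, "q1": q1, "median": med, "q3": q3, "max": hi}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# proximity function and outlier flags
# ---------------------------------------------------------------------

def proximity_of(d2_to_sample: np.ndarray, vd: float) -> float:
    """phi of an external individual given its squared distances to the sample."""
    d2 = np.asarray(d2_to_sample, dtype=float)
    return float(d2.mean() - vd)


def proximity_track(series: DistanceSeries, include_self: bool = True) -> ProximityTrack:
    """The dynamic proximity function phi for every sample entity and time.

    For a sample member the mean runs over the full sample including the
    zero self-distance, which makes the entity-average of phi equal VD(t)
    exactly at every time.  ``include_self=False`` is a sensitivity
    variant averaging over the other n-1 entities only.
    """
    n = series.n
    phi = np.empty((n, len(series.times)))
    for j, m in enumerate(series.matrices):
        vd = m.gv
        row_sum = m.values.sum(axis=1)
        phi[:, j] = (row_sum / n if include_self else row_sum / (n - 1)) - vd
    return ProximityTrack(
        series.labels, tuple(series.times), phi, include_self=include_self
    )


def flag_outliers(
    track: ProximityTrack, percentile: float = 90.0, pooled: bool = False
) -> ProximityTrack:
    """Flag (entity, time) cells with phi strictly above a percentile cut.

    The threshold is the linear-interpolation percentile of the n phi
    values at each time (default), or of all n*N values pooled over the
    period when ``pooled`` is set.  Strict inequality: equal-phi samples
    produce no flags.
    """
    if not 0.0 <= percentile < 100.0:
        raise PanelError(f"percentile must be in [0, 100), got {percentile}")
    if pooled:
        cut = float(np.percentile(track.phi, percentile))
        thresholds = np.full(len(track.times), cut)
    else:
        thresholds = np.percentile(track.phi, percentile, axis=0)
    flags = track.phi > thresholds[None, :]
    return replace(track, percentile=percentile, thresholds=thresholds, flags=flags)
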