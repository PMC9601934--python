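"""Robust Gower distance components, geometric variability and the joint metric.

For a snapshot of ``n`` individuals the method builds one squared-distance
matrix per data source: a robust Mahalanobis distance for quantitative
blocks, the distance associated with Jaccard's similarity coefficient for
binary blocks, and the Hamming distance for categorical blocks.  Each
component is rescaled to unit *geometric variability*

    VD = (1/(2 n^2)) * sum_ij d2[i, j],

which amounts to a change of measurement unit, and the components are
summed into the joint robust metric D(t).  By linearity of VD, the joint
matrix has VD = m, the number of combined sources.

All matrices hold SQUARED distances; square roots are presentation-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.covariance import LedoitWolf, MinCovDet

from .panel import MixedPanel, PanelError

logger = logging.getLogger("dynagower")

__all__ = [
    "SquaredDistanceMatrix",
    "DistanceSeries",
    "DegenerateSourceError",
    "DegenerateVariableError",
    "geometric_variability",
    "normalize_unit_gv",
    "robust_covariance",
    "mahalanobis_matrix",
    "cityblock_gower_matrix",
    "jaccard_matrix",
    "hamming_matrix",
    "joint_metric_at_time",
    "distance_series",
]

GROUPINGS = ("by_type", "by_source", "by_type_and_source")


class DegenerateSourceError(PanelError):
    """A source's component matrix has zero geometric variability."""


class DegenerateVariableError(PanelError):
    """A variable carries no information (zero variance / zero range)."""


@dataclass(frozen=True)
class SquaredDistanceMatrix:
    """An ``n x n`` matrix of squared pairwise distances with entity labels.

    ``component`` records which metric produced it (``mahalanobis_robust``,
    ``cityblock_classical``, ``jaccard``, ``hamming`` or ``joint``); ``gv``
    caches its geometric variability.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    component: str = "joint"
    gv: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise PanelError(f"distance matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.labels):
            raise PanelError("label count does not match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-8):
            raise PanelError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-10):
            raise PanelError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-10):
            raise PanelError("squared distances must be nonnegative")
        # enforce exact symmetry / zero diagonal / nonnegativity
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "gv", geometric_variability(v))

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown entity {label!r}") from None

    def upper_values(self) -> np.ndarray:
        """The n(n-1)/2 strict upper-triangle entries in condensed order."""
        return squareform(self.values, checks=False)


@dataclass
class DistanceSeries:
    """One joint squared-distance matrix per time point.

    ``components_raw`` and ``components_normalized`` map each source key to
    the per-time component matrices before / after unit-gv rescaling; the
    raw ones carry the variability signal tracked over time.  ``dropped``
    lists times skipped under the lenient failure mode.
    """

    times: list[str]
    matrices: list[SquaredDistanceMatrix]
    components_raw: dict[str, list[SquaredDistanceMatrix]] = field(default_factory=dict)
    components_normalized: dict[str, list[SquaredDistanceMatrix]] = field(
        default_factory=dict
    )
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.matrices):
            raise PanelError("one matrix per time required")
        labels = self.matrices[0].labels if self.matrices else ()
        for m in self.matrices:
            if m.labels != labels:
                raise PanelError("all matrices in a series must share entity labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.matrices[0].labels

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def sources(self) -> list[str]:
        return list(self.components_raw)

    def at(self, t: str) -> SquaredDistanceMatrix:
        try:
            return self.matrices[self.times.index(t)]
        except ValueError:
            raise KeyError(f"time {t!r} not in series") from None


# ---------------------------------------------------------------------
# geometric variability
# ---------------------------------------------------------------------

def geometric_variability(D: SquaredDistanceMatrix | np.ndarray) -> float:
    """Geometric variability VD = (1/(2 n^2)) * grand sum of squared distances.

    Generalizes total variance and is linear in the matrix:
    ``gv(A + B) == gv(A) + gv(B)``.
    """
    v = D.values if isinstance(D, SquaredDistanceMatrix) else np.asarray(D, float)
    n = v.shape[0]
    return float(v.sum() / (2.0 * n * n))


def normalize_unit_gv(D: SquaredDistanceMatrix, source: str = "") -> SquaredDistanceMatrix:
    """Rescale a squared-distance matrix to unit geometric variability.

    Multiplying squared distances by a positive constant is a change of
    measurement unit, so this is exact, idempotent and scale-equivariant.
    A zero-gv matrix (all individuals identical under the component) has
    no defined unit and raises :class:`DegenerateSourceError`.
    """
    g = D.gv
    if g <= 0.0:
        name = source or D.component
        raise DegenerateSourceError(
            f"component {name!r} has zero geometric variability; "
            "all individuals coincide under this source"
        )
    return replace(D, values=D.values / g)


# ---------------------------------------------------------------------
# component metrics
# ---------------------------------------------------------------------

def _check_variances(X: np.ndarray, names: Sequence[str] | None) -> None:
    spread = X.max(axis=0) - X.min(axis=0)
    degenerate = np.flatnonzero(spread == 0.0)
    if degenerate.size:
        which = (
            [names[i] for i in degenerate] if names is not None else list(degenerate)
        )
        raise DegenerateVariableError(f"zero-variance column(s): {which}")


def robust_covariance(
    X: np.ndarray,
    support_fraction: float | None = None,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Robust scatter and location for a quantitative ``n x q`` table.

    The estimator is the reweighted Minimum Covariance Determinant (MCD)
    with default support fraction ``floor((n+q+1)/2)/n``.  When the MCD is
    infeasible (``n < q + 2``) or yields a singular scatter, the fallback
    ladder is Ledoit-Wolf shrinkage toward a scaled identity; consumers may
    pseudo-invert as a last resort.  Returns ``(scatter, location, method)``
    with ``method in {"mcd", "shrinkage"}``.
    """
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    _check_variances(X, names)
    # canonical (lexicographic) row order: the estimate must not depend on
    # the order individuals appear in the input file
    X = X[np.lexsort(X.T[::-1])]
    if n >= q + 2:
        try:
            mcd = MinCovDet(
                support_fraction=support_fraction, random_state=seed
            ).fit(X)
            scatter = np.asarray(mcd.covariance_)
            if _is_positive_definite(scatter):
                return scatter, np.asarray(mcd.location_), "mcd"
            logger.warning("MCD scatter singular (n=%d, q=%d); shrinkage fallback", n, q)
        except Exception as exc:  # pragma: no cover - rare numerical failure
            logger.warning("MCD failed (%s); shrinkage fallback", exc)
    else:
        logger.warning(
            "n=%d too small for MCD with q=%d variables; shrinkage fallback", n, q
        )
    lw = LedoitWolf().fit(X)
    return np.asarray(lw.covariance_), np.asarray(lw.location_), "shrinkage"


def _is_positive_definite(S: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(S)
        return True
    except np.linalg.LinAlgError:
        return False


def mahalanobis_matrix(
    X: np.ndarray,
    scatter: np.ndarray,
    labels: Sequence[str] | None = None,
    allow_pinv: bool = False,
) -> SquaredDistanceMatrix:
    """Squared Mahalanobis distances ``(zi - zj)' S^{-1} (zi - zj)``.

    With ``S = I`` this reduces to squared Euclidean distance.  A singular
    scatter raises unless ``allow_pinv`` permits the pseudo-inverse.
    """
    X = np.asarray(X, dtype=float)
    scatter = np.asarray(scatter, dtype=float)
    if allow_pinv or not _is_positive_definite(scatter):
        if not allow_pinv:
            raise np.linalg.LinAlgError("scatter matrix is singular")
        VI = np.linalg.pinv(scatter, hermitian=True)
    else:
        VI = np.linalg.inv(scatter)
    VI = (VI + VI.T) / 2.0
    # factor VI = L L' so squared Mahalanobis = squared Euclidean in X @ L
    w, U = np.linalg.eigh(VI)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    d2 = squareform(pdist(X @ L, metric="sqeuclidean"))
    return SquaredDistanceMatrix(
        _labels_for(X, labels), d2, component="mahalanobis_robust"
    )


def cityblock_gower_matrix(
    X: np.ndarray, labels: Sequence[str] | None = None, names: Sequence[str] | None = None
) -> SquaredDistanceMatrix:
    """Classical range-normalized city-block component (comparison baseline).

    Entry ``(i, j) = (1/q) * sum_k |x_ik - x_jk| / R_k`` with ``R_k`` the
    column range, stored directly as the squared distance (Gower's
    ``d^2 = 1 - s``); entries lie in ``[0, 1]``.
    """
    X = np.asarray(X, dtype=float)
    _check_variances(X, names)
    ranges = X.max(axis=0) - X.min(axis=0)
    q = X.shape[1]
    d2 = squareform(pdist(X / ranges, metric="cityblock")) / q
    return SquaredDistanceMatrix(
        _labels_for(X, labels), d2, component="cityblock_classical"
    )


def jaccard_matrix(
    B: np.ndarray, labels: Sequence[str] | None = None
) -> SquaredDistanceMatrix:
    """Squared distance ``1 - s_J`` from Jaccard's similarity coefficient.

    ``s_J = a / (a + b + c)`` where ``a`` counts shared ones and ``b + c``
    counts mismatches; double zeros are excluded from the denominator.  A
    pair with empty denominator (both rows all zero) takes ``s_J := 1``
    (distance 0), treating double absence as non-information.
    """
    B = np.asarray(B, dtype=float)
    if not np.isin(B, (0.0, 1.0)).all():
        raise PanelError("binary table must contain only 0/1 values")
    a = B @ B.T  # shared ones
    ones = B.sum(axis=1)
    mismatches = ones[:, None] + ones[None, :] - 2.0 * a
    denom = a + mismatches
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), 1.0)
    return SquaredDistanceMatrix(_labels_for(B, labels), 1.0 - s, component="jaccard")


def hamming_matrix(
    C: np.ndarray, labels: Sequence[str] | None = None
) -> SquaredDistanceMatrix:
    """Squared distance = proportion of mismatching categorical variables."""
    C = np.asarray(C, dtype=object)
    if C.ndim != 2 or C.shape[1] < 1:
        raise PanelError("categorical table must be 2-D with q >= 1 columns")
    n, q = C.shape
    d2 = np.zeros((n, n))
    for k in range(q):
        col = C[:, k]
        d2 += (col[:, None] != col[None, :]).astype(float)
    return SquaredDistanceMatrix(_labels_for(C, labels), d2 / q, component="hamming")


def _labels_for(X: np.ndarray, labels: Sequence[str] | None) -> tuple[str, ...]:
    if labels is None:
        return tuple(f"i{k}" for k in range(X.shape[0]))
    return tuple(labels)


# ---------------------------------------------------------------------
# joint robust metric
# ---------------------------------------------------------------------

def group_variables(panel: MixedPanel, grouping: str) -> dict[str, tuple[str, list[str]]]:
    """Partition variables into component groups.

    Returns an ordered mapping ``key -> (vtype, variable names)``.  Under
    ``by_source``, a source mixing variable types is split by type into
    sub-blocks keyed ``source:vtype`` (each sub-block is normalized
    separately and counts toward ``m``).
    """
    if grouping not in GROUPINGS:
        raise PanelError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    groups: dict[str, tuple[str, list[str]]] = {}
    if grouping == "by_type":
        for vtype in ("quantitative", "binary", "categorical"):
            names = [v.name for v in panel.variables if v.vtype == vtype]
            if names:
                groups[vtype] = (vtype, names)
        return groups
    for source in panel.sources:
        block = [v for v in panel.variables if v.source == source]
        vtypes = []
        for v in block:
            if v.vtype not in vtypes:
                vtypes.append(v.vtype)
        split = grouping == "by_type_and_source" or len(vtypes) > 1
        for vtype in vtypes:
            key = f"{source}:{vtype}" if split else source
            groups[key] = (vtype, [v.name for v in block if v.vtype == vtype])
    return groups


def _component_for_group(
    panel: MixedPanel,
    t: str,
    vtype: str,
    names: list[str],
    metric: str,
    scatter: np.ndarray | None,
    support_fraction: float | None,
    seed: int,
) -> SquaredDistanceMatrix:
    X = panel.values_by_type(t, names)
    labels = panel.entities
    if vtype == "quantitative":
        if metric == "cityblock":
            return cityblock_gower_matrix(
                X.astype(float), labels=labels, names=names
            )
        if scatter is None:
            scatter, _, method = robust_covariance(
                X.astype(float), support_fraction=support_fraction, seed=seed, names=names
            )
        else:
            method = "pooled"
        return mahalanobis_matrix(
            X.astype(float), scatter, labels=labels, allow_pinv=method == "shrinkage"
        )
    if vtype == "binary":
        return jaccard_matrix(X.astype(float), labels=labels)
    return hamming_matrix(X, labels=labels)


def joint_metric_at_time(
    panel: MixedPanel,
    t: str,
    grouping: str = "by_source",
    metric: str = "robust",
    support_fraction: float | None = None,
    seed: int = 0,
    scatters: Mapping[str, np.ndarray] | None = None,
) -> tuple[
    SquaredDistanceMatrix,
    dict[str, SquaredDistanceMatrix],
    dict[str, SquaredDistanceMatrix],
]:
    """The joint robust metric D(t) and its per-source components at time ``t``.

    Each group's component matrix (robust Mahalanobis / Jaccard / Hamming
    by type; ``metric="cityblock"`` swaps in the classical baseline for
    quantitative groups) is normalized to unit geometric variability and
    the m normalized components are summed, so VD of the result equals m.

    ``scatters`` optionally supplies a precomputed (e.g. pooled) scatter
    per quantitative group key.  Returns
    ``(joint, raw components, normalized components)``.
    """
    if metric not in ("robust", "cityblock"):
        raise PanelError(f"metric must be 'robust' or 'cityblock', got {metric!r}")
    groups = group_variables(panel, grouping)
    raw: dict[str, SquaredDistanceMatrix] = {}
    norm: dict[str, SquaredDistanceMatrix] = {}
    total = np.zeros((panel.n, panel.n))
    for key, (vtype, names) in groups.items():
        scatter = scatters.get(key) if scatters else None
        try:
            component = _component_for_group(
                panel, t, vtype, names, metric, scatter, support_fraction, seed
            )
            normalized = normalize_unit_gv(component, source=key)
        except (DegenerateSourceError, DegenerateVariableError) as exc:
            raise type(exc)(f"group {key!r} at time {t!r}: {exc}") from exc
        raw[key] = component
        norm[key] = normalized
        total += normalized.values
    joint = SquaredDistanceMatrix(tuple(panel.entities), total, component="joint")
    return joint, raw, norm


def pooled_scatters(
    panel: MixedPanel,
    grouping: str,
    support_fraction: float | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """One robust scatter per quantitative group from all N*n stacked rows.

    Unlike the per-time estimate, a pooled scatter keeps the measurement
    unit fixed across time, so per-time dispersion changes remain visible
    in the raw component's geometric variability.
    """
    out = {}
    for key, (vtype, names) in group_variables(panel, grouping).items():
        if vtype != "quantitative":
            continue
        stacked = np.vstack(
            [panel.values_by_type(t, names).astype(float) for t in panel.times]
        )
        scatter, _, _ = robust_covariance(
            stacked, support_fraction=support_fraction, seed=seed, names=names
        )
        out[key] = scatter
    return out


def distance_series(
    panel: MixedPanel,
    grouping: str = "by_source",
    metric: str = "robust",
    scatter_mode: str = "per_time",
    support_fraction: float | None = None,
    seed: int = 0,
    strict: bool = True,
) -> DistanceSeries:
    """Joint squared-distance matrices {D(t) : t in T} for a whole panel.

    ``scatter_mode`` is ``"per_time"`` (robust scatter re-estimated from
    each snapshot; the default) or ``"pooled"`` (one scatter per
    quantitative group from all rows).  In strict mode the first per-time
    failure aborts naming the time; in lenient mode failed times are
    dropped and recorded in ``series.dropped``.
    """
    if scatter_mode not in ("per_time", "pooled"):
        raise PanelError(f"scatter_mode must be per_time|pooled, got {scatter_mode!r}")
    scatters = (
        pooled_scatters(panel, grouping, support_fraction, seed)
        if scatter_mode == "pooled" and metric == "robust"
        else None
    )
    times: list[str] = []
    matrices: list[SquaredDistanceMatrix] = []
    raw: dict[str, list[SquaredDistanceMatrix]] = {}
    norm: dict[str, list[SquaredDistanceMatrix]] = {}
    dropped: list[tuple[str, str]] = []
    for t in panel.times:
        try:
            joint, raw_t, norm_t = joint_metric_at_time(
                panel,
                t,
                grouping=grouping,
                metric=metric,
                support_fraction=support_fraction,
                seed=seed,
                scatters=scatters,
            )
        except PanelError as exc:
            if strict:
                raise
            logger.warning("dropping time %r: %s", t, exc)
            dropped.append((t, str(exc)))
            continue
        times.append(t)
        matrices.append(joint)
        for key, mat in raw_t.items():
            raw.setdefault(key, []).append(mat)
            norm.setdefault(key, []).append(norm_t[key])
    if not matrices:
        raise PanelError("no time point produced a distance matrix")
    return DistanceSeries(times, matrices, raw, norm, dropped)
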