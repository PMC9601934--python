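"""Seeded synthetic mixed-type panels with known planted structure.

The generator emulates the structure of a multi-source epidemiological
panel — 25 entities followed weekly, with quantitative blocks
(case/hospitalization-like counts, 0-100 policy indices, mobility
percentage changes), plus optional binary and multi-state categorical
blocks — without attempting to mimic real epidemic curves.  Structure can
be planted and later recovered: location-outlier entities (shifted a
stated multiple of each variable's true SD) and per-time covariance
spikes in one source.

One integer seed drives everything; sub-streams per block are derived
from it deterministically, so an identical spec yields a bit-identical
panel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .distance import distance_series
from .panel import MixedPanel, PanelError, VariableSpec
from .tracks import proximity_track, variability_tracks

__all__ = [
    "QuantitativeBlock",
    "BinaryBlock",
    "CategoricalBlock",
    "PlantedOutlier",
    "VarianceSpike",
    "PanelSimSpec",
    "generate_panel",
    "covid_like_spec",
    "mixed_type_spec",
    "outlier_recovery_spec",
    "outlier_recovery_rate",
    "spike_detection_rate",
]


@dataclass(frozen=True)
class QuantitativeBlock:
    """A block of correlated quantitative variables from one source.

    ``mean`` is the (N, q) per-time mean trajectory, ``cov`` the (q, q)
    covariance; ``clip`` optionally bounds values (index-like variables on
    a 0-100 scale are generated unbounded then clipped).
    """

    source: str
    q: int
    mean: tuple  # nested tuples, (N, q)
    cov: tuple  # nested tuples, (q, q)
    clip: tuple[float, float] | None = None


@dataclass(frozen=True)
class BinaryBlock:
    source: str
    q: int
    p: tuple  # (q,) Bernoulli probabilities
    drift: float = 0.0  # per-time additive drift on p, clipped to (0.01, 0.99)


@dataclass(frozen=True)
class CategoricalBlock:
    source: str
    q: int
    alphabet_sizes: tuple[int, ...]
    probs: tuple  # per variable, tuple of category probabilities


@dataclass(frozen=True)
class PlantedOutlier:
    """Shift one entity by ``shift`` true SDs in every quantitative variable.

    ``times`` lists affected time indices (None = all).  ``signs``
    optionally gives a per-source mapping of +-1 direction patterns; by
    default the shift is +shift*SD in every variable.
    """

    entity_index: int
    shift: float
    times: tuple[int, ...] | None = None
    signs: tuple | None = None  # flat tuple of +-1 per quantitative variable


@dataclass(frozen=True)
class VarianceSpike:
    """Multiply one source's covariance by ``scale`` at one time index."""

    source: str
    time_index: int
    scale: float


@dataclass(frozen=True)
class PanelSimSpec:
    """Full description of a synthetic panel draw (JSON-serializable)."""

    n_entities: int
    n_times: int
    quantitative_blocks: tuple[QuantitativeBlock, ...]
    binary_block: BinaryBlock | None = None
    categorical_block: CategoricalBlock | None = None
    outliers: tuple[PlantedOutlier, ...] = ()
    variance_spikes: tuple[VarianceSpike, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_entities < 2 or self.n_times < 1:
            raise PanelError("need n_entities >= 2 and n_times >= 1")
        for b in self.quantitative_blocks:
            mean = np.asarray(b.mean, dtype=float)
            cov = np.asarray(b.cov, dtype=float)
            if mean.shape != (self.n_times, b.q):
                raise PanelError(
                    f"block {b.source!r}: mean shape {mean.shape} != (N, q)"
                )
            if cov.shape != (b.q, b.q):
                raise PanelError(f"block {b.source!r}: cov shape {cov.shape} != (q, q)")
        if self.binary_block is not None:
            p = np.asarray(self.binary_block.p, dtype=float)
            if p.shape != (self.binary_block.q,) or not ((p > 0) & (p < 1)).all():
                raise PanelError("binary probabilities must be in (0, 1), one per variable")
        if self.categorical_block is not None:
            c = self.categorical_block
            if len(c.alphabet_sizes) != c.q or len(c.probs) != c.q:
                raise PanelError("categorical block dimensions inconsistent")
        for o in self.outliers:
            if not 0 <= o.entity_index < self.n_entities:
                raise PanelError(f"outlier entity index {o.entity_index} out of range")
            if o.shift <= 0:
                raise PanelError("outlier shift must be > 0")
        sources = [b.source for b in self.quantitative_blocks]
        for s in self.variance_spikes:
            if s.source not in sources:
                raise PanelError(f"variance spike names unknown source {s.source!r}")
            if not 0 <= s.time_index < self.n_times:
                raise PanelError(f"spike time index {s.time_index} out of range")
            if s.scale <= 1:
                raise PanelError("spike scale factor must be > 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _labels(prefix: str, count: int) -> list[str]:
    width = len(str(count))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(count)]


def generate_panel(spec: PanelSimSpec) -> MixedPanel:
    """Draw a :class:`MixedPanel` from a simulation spec.

    Quantitative blocks are per-time multivariate normal draws; binary
    variables are Bernoulli; categoricals are multinomial over letter
    alphabets.  Planted outliers are shifted by ``shift`` times each
    variable's true SD (the square root of the generating covariance
    diagonal, including any spike in force at that time) before clipping.
    """
    spec.validate()
    n, N = spec.n_entities, spec.n_times
    entities = _labels("E", n)
    times = _labels("t", N)

    streams = np.random.SeedSequence(spec.seed).spawn(
        len(spec.quantitative_blocks) + 2
    )
    variables: list[VariableSpec] = []
    columns: dict[str, np.ndarray] = {}  # name -> (n, N) array

    spikes = {(s.source, s.time_index): s.scale for s in spec.variance_spikes}

    flat_q = 0
    for b_idx, block in enumerate(spec.quantitative_blocks):
        rng = np.random.default_rng(streams[b_idx])
        mean = np.asarray(block.mean, dtype=float)
        cov = np.asarray(block.cov, dtype=float)
        names = [f"{block.source}_q{k + 1}" for k in range(block.q)]
        data = np.empty((n, N, block.q))
        for j in range(N):
            cov_t = cov * spikes.get((block.source, j), 1.0)
            data[:, j, :] = rng.multivariate_normal(
                mean[j], cov_t, size=n, method="cholesky"
            )
            sd_t = np.sqrt(np.diag(cov_t))
            for o in spec.outliers:
                if o.times is not None and j not in o.times:
                    continue
                signs = (
                    np.asarray(o.signs, dtype=float)[flat_q : flat_q + block.q]
                    if o.signs is not None
                    else np.ones(block.q)
                )
                data[o.entity_index, j, :] += o.shift * sd_t * signs
        if block.clip is not None:
            data = np.clip(data, *block.clip)
        for k, name in enumerate(names):
            variables.append(VariableSpec(name, "quantitative", block.source))
            columns[name] = data[:, :, k]
        flat_q += block.q

    if spec.binary_block is not None:
        b = spec.binary_block
        rng = np.random.default_rng(streams[-2])
        p = np.asarray(b.p, dtype=float)
        for k in range(b.q):
            name = f"{b.source}_b{k + 1}"
            variables.append(VariableSpec(name, "binary", b.source))
            pt = np.clip(p[k] + b.drift * np.arange(N), 0.01, 0.99)
            columns[name] = (rng.random((n, N)) < pt[None, :]).astype(int)

    if spec.categorical_block is not None:
        c = spec.categorical_block
        rng = np.random.default_rng(streams[-1])
        for k in range(c.q):
            name = f"{c.source}_c{k + 1}"
            variables.append(VariableSpec(name, "categorical", c.source))
            probs = np.asarray(c.probs[k], dtype=float)
            probs = probs / probs.sum()
            draws = rng.choice(len(probs), size=(n, N), p=probs)
            alphabet = np.array([chr(ord("a") + m) for m in range(len(probs))])
            columns[name] = alphabet[draws]

    frames = {}
    for j, t in enumerate(times):
        frames[t] = pd.DataFrame(
            {name: columns[name][:, j] for name in (v.name for v in variables)},
            index=entities,
        )
    return MixedPanel(entities, times, variables, frames)


# ---------------------------------------------------------------------
# canonical specs
# ---------------------------------------------------------------------

def _random_correlation(rng: np.random.Generator, q: int, sd: np.ndarray) -> np.ndarray:
    """A well-conditioned random covariance with the given SDs."""
    A = rng.normal(size=(q, q + 3))
    C = A @ A.T
    d = np.sqrt(np.diag(C))
    corr = C / np.outer(d, d)
    corr = 0.6 * corr + 0.4 * np.eye(q)  # keep away from singularity
    return corr * np.outer(sd, sd)


def _smooth_trajectories(
    rng: np.random.Generator, N: int, q: int, base: float, amplitude: float
) -> np.ndarray:
    """Per-variable smooth mean curves: baseline + trend + one sinusoid."""
    t = np.linspace(0.0, 1.0, N)[:, None]
    level = base + rng.normal(scale=0.2 * amplitude, size=q)[None, :]
    trend = rng.normal(scale=amplitude, size=q)[None, :] * t
    phase = rng.uniform(0, 2 * np.pi, size=q)[None, :]
    freq = rng.integers(1, 4, size=q)[None, :]
    wave = amplitude * 0.5 * np.sin(2 * np.pi * freq * t + phase)
    return level + trend + wave


def covid_like_spec(seed: int = 0) -> PanelSimSpec:
    """Canonical pandemic-panel fixture: 25 entities x 59 weeks x 15 variables.

    Three quantitative sources mirror the application's structure: six
    "health" variables (incidence/hospitalization-like levels), three
    "stringency" policy indices clipped to the 0-100 scale, and six
    "mobility" percentage-change variables.  One documented outlier
    (entity index 24, shift 8 SD, all weeks) and one variance spike
    ("health" x4 at week index 29) are planted by default.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    N = 59
    health_sd = rng.uniform(1.0, 3.0, size=6)
    stringency_sd = rng.uniform(5.0, 10.0, size=3)
    mobility_sd = rng.uniform(5.0, 15.0, size=6)
    blocks = (
        QuantitativeBlock(
            "health",
            6,
            _to_tuple(_smooth_trajectories(rng, N, 6, base=10.0, amplitude=4.0)),
            _to_tuple(_random_correlation(rng, 6, health_sd)),
        ),
        QuantitativeBlock(
            "stringency",
            3,
            _to_tuple(_smooth_trajectories(rng, N, 3, base=55.0, amplitude=15.0)),
            _to_tuple(_random_correlation(rng, 3, stringency_sd)),
            clip=(0.0, 100.0),
        ),
        QuantitativeBlock(
            "mobility",
            6,
            _to_tuple(_smooth_trajectories(rng, N, 6, base=-10.0, amplitude=20.0)),
            _to_tuple(_random_correlation(rng, 6, mobility_sd)),
        ),
    )
    return PanelSimSpec(
        n_entities=25,
        n_times=N,
        quantitative_blocks=blocks,
        outliers=(PlantedOutlier(entity_index=24, shift=8.0),),
        variance_spikes=(VarianceSpike("health", 29, 4.0),),
        seed=seed,
    )


def mixed_type_spec(seed: int = 0) -> PanelSimSpec:
    """Small all-three-types fixture (n=10, N=4) exercising every component."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11)))
    N = 4
    sd = rng.uniform(0.5, 2.0, size=3)
    return PanelSimSpec(
        n_entities=10,
        n_times=N,
        quantitative_blocks=(
            QuantitativeBlock(
                "clinical",
                3,
                _to_tuple(_smooth_trajectories(rng, N, 3, base=0.0, amplitude=1.0)),
                _to_tuple(_random_correlation(rng, 3, sd)),
            ),
        ),
        binary_block=BinaryBlock("symptoms", 4, tuple(rng.uniform(0.25, 0.75, size=4))),
        categorical_block=CategoricalBlock(
            "strain",
            2,
            (3, 4),
            (
                tuple(rng.dirichlet(np.ones(3) * 4)),
                tuple(rng.dirichlet(np.ones(4) * 4)),
            ),
        ),
        seed=seed,
    )


def _to_tuple(a: np.ndarray) -> tuple:
    return tuple(map(tuple, np.asarray(a, dtype=float)))


# ---------------------------------------------------------------------
# planted-structure recovery experiments
# ---------------------------------------------------------------------

def outlier_recovery_spec(
    seed: int,
    n: int = 25,
    N: int = 10,
    shift: float = 8.0,
    contamination: float = 0.0,
) -> PanelSimSpec:
    """One replicate spec for the outlier-recovery experiment.

    A single quantitative source of six correlated variables; the focal
    outlier (entity index 0) is shifted +shift SD in every variable.
    Under contamination, additional entities (to a total of
    ``round(contamination * n)`` contaminated ones) form a masking
    cluster: shifted 6 SD in the same direction as the focal outlier, the
    classic scenario where a non-robust fit absorbs the cluster while the
    robust fit keeps it at distance.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBEEF)))
    q = 6
    sd = rng.uniform(1.0, 3.0, size=q)
    block = QuantitativeBlock(
        "health",
        q,
        _to_tuple(_smooth_trajectories(rng, N, q, base=10.0, amplitude=4.0)),
        _to_tuple(_random_correlation(rng, q, sd)),
    )
    outliers = [PlantedOutlier(entity_index=0, shift=shift)]
    n_contam = int(round(contamination * n))
    for extra in range(1, n_contam):
        outliers.append(PlantedOutlier(entity_index=extra, shift=6.0))
    return PanelSimSpec(
        n_entities=n,
        n_times=N,
        quantitative_blocks=(block,),
        outliers=tuple(outliers),
        seed=seed,
    )


def outlier_recovery_rate(
    n_reps: int = 200,
    seed: int = 0,
    contamination: float = 0.0,
    metric: str = "robust",
    n: int = 25,
    N: int = 10,
    shift: float = 8.0,
) -> float:
    """Fraction of replicates where the focal planted outlier wins on phi.

    Each replicate draws a fresh panel, computes the distance series with
    the requested quantitative metric, and checks whether the focal
    entity attains the maximum time-averaged proximity value.
    """
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    hits = 0
    for rs in rep_seeds:
        spec = outlier_recovery_spec(
            int(rs), n=n, N=N, shift=shift, contamination=contamination
        )
        panel = generate_panel(spec)
        series = distance_series(panel, metric=metric, seed=int(rs) % (2**31))
        mean_phi = proximity_track(series).phi.mean(axis=1)
        hits += int(np.argmax(mean_phi) == 0)
    return hits / n_reps


def spike_detection_rate(
    n_reps: int = 100,
    seed: int = 0,
    n: int = 25,
    N: int = 10,
    spike_time: int = 5,
    scale: float = 4.0,
) -> float:
    """Fraction of replicates where a x``scale`` covariance spike is the track max.

    The variability track is computed from the raw Mahalanobis component
    under the *pooled* scatter mode: a per-time affine-equivariant
    scatter would absorb the spike exactly (Mahalanobis distances are
    scale-free), whereas a pooled scatter keeps the measurement unit
    fixed so the spiked week stands out.
    """
    rep_seeds = np.random.SeedSequence((seed, 0x5717)).generate_state(n_reps) % (2**31)
    hits = 0
    for rs in rep_seeds:
        rng = np.random.default_rng(np.random.SeedSequence((int(rs), 0xBEEF)))
        q = 6
        sd = rng.uniform(1.0, 3.0, size=q)
        spec = PanelSimSpec(
            n_entities=n,
            n_times=N,
            quantitative_blocks=(
                QuantitativeBlock(
                    "health",
                    q,
                    _to_tuple(_smooth_trajectories(rng, N, q, base=10.0, amplitude=4.0)),
                    _to_tuple(_random_correlation(rng, q, sd)),
                ),
            ),
            variance_spikes=(VarianceSpike("health", spike_time, scale),),
            seed=int(rs),
        )
        panel = generate_panel(spec)
        series = distance_series(
            panel, scatter_mode="pooled", seed=int(rs) % (2**31)
        )
        track = variability_tracks(series)[0]
        hits += int(np.argmax(track.values) == spike_time)
    return hits / n_reps
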