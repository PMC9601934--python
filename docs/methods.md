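# Methods

## Model and procedure

For each time `t ∈ {1, …, N}` the package observes `n` individuals on
`p` mixed-type variables and builds a matrix `D(t)` of **squared**
pairwise distances.  Squared distances are the native unit throughout —
geometric variability, the proximity function and classical MDS are all
defined on them — and square roots appear only as a presentation option.

Variables are partitioned into `m` groups by variable type, by source
label, or by both.  A source that mixes types under `by_source` grouping
is split internally into one sub-block per type, each normalized
separately; `m` counts the sub-blocks.  Per group the component metric
is:

| type | component (squared distance) |
|---|---|
| quantitative | robust Mahalanobis `(zi−zj)ᵀ S⁻¹ (zi−zj)` |
| binary | `1 − s_J`, Jaccard similarity with double zeros excluded |
| categorical | proportion of mismatching variables (Hamming) |

Each component is divided by its geometric variability
`VD = (1/2n²) Σᵢⱼ d²ᵢⱼ` so that `VDk(t) = 1`, then the components are
summed.  Because VD is linear, the joint matrix has `VD(t) = m`
identically; this and the mean-φ identity below are exact algebraic
invariants and are asserted at 1e-10/1e-9 in the tests only to allow for
float accumulation.

The proximity function of an individual with squared distances
`d²(z0, zi)` to the sample is `φ = (1/n) Σᵢ d² − VD(t)`.  For a sample
member the sum runs over the full sample *including* its own zero
self-distance; with that convention the entity-average of φ equals
`VD(t)` exactly at every `t` (substitute the definition of VD and
exchange sums).  An exclude-self variant (divide by `n−1`) is available
as a sensitivity flag and is uniformly no smaller.

## Tunable parameters

- **grouping** (`by_source` default): how variables form components.
  The canonical panel has three all-quantitative sources, so `by_source`
  and `by_type_and_source` coincide there.
- **robust scatter**: reweighted Minimum Covariance Determinant,
  support fraction defaulting to `⌊(n+q+1)/2⌋/n`, subsampling seed 0
  (configurable; fixed seed gives bit-reproducible matrices).  The MCD
  is fitted on lexicographically sorted rows so the estimate — and hence
  every distance matrix — is invariant to the order individuals appear
  in the input file.
- **fallback ladder**: if `n < q+2` or the MCD scatter is singular,
  Ledoit–Wolf shrinkage toward a scaled identity is used (logged); the
  pseudo-inverse is the last resort at the Mahalanobis step.
- **scatter_mode** (`per_time` default | `pooled`): whether `S` is
  re-estimated from each `n×q` snapshot or once from all `N·n` stacked
  rows.  See the affine-invariance note below.
- **percentile** (90 default) and **pooled** flag for outlier
  thresholds: the cut is the linear-interpolation percentile of the `n`
  φ values at each time (or of all `n·N` values pooled); flags use
  strict inequality, so a tie at the threshold never flags.
- **MDS k** (2 default) and **alignment** (off by default): consecutive
  maps can be aligned by unscaled orthogonal Procrustes to the previous
  (chained); alignment changes no within-time distance, it only removes
  the rotation/reflection ambiguity that makes unaligned animations
  flicker.  Off by default so the plain per-time maps are what you get
  unless you ask.
- **marker sizes**: any quantitative variable, min-max rescaled to
  [1, 5] per time; a constant variable maps to the midpoint 3.

## Numerical conventions

- Quartiles, percentiles and thresholds use linear interpolation
  between order statistics (numpy's default, the "type 7" convention);
  no convention is canonical for the method, a fixed one makes outputs
  bit-reproducible.
- Arg-extreme ties break to the lexicographically smallest entity pair
  (the condensed upper-triangle order is already lexicographic, so the
  first minimum/maximum wins).
- A pair of all-zero binary rows has an empty Jaccard denominator; the
  convention is `s_J := 1` (distance 0): double absence is treated as
  non-information rather than NaN.
- A component with `VD = 0` (all individuals identical under that
  source at that time) has no unit and raises a degenerate-source error
  naming group and time; strict mode aborts the series there, lenient
  mode drops the time and records it.
- MDS eigenvalues are kept when `> 1e-9 ×` the largest magnitude;
  negative eigenvalues (the joint metric need not be Euclidean) are
  dropped and their share of the absolute eigenvalue mass is reported
  as a diagnostic.  Coordinate signs are fixed by making each column's
  largest-magnitude entry nonnegative.  A matrix with no positive
  eigenvalues returns all-zero coordinates.
- Matrix CSVs are written at 12 significant digits (round-trip error
  < 1e-10 at the scales produced); panel CSVs use shortest-round-trip
  float formatting and are re-read with correctly-rounded parsing, so a
  write/read cycle is lossless.

## Affine invariance and the variability track

The Mahalanobis distance is affine invariant: if the time-`t` snapshot
is rescaled and the scatter is re-estimated from that same snapshot by
an affine-equivariant estimator (the MCD is one), the distances — and
hence the raw component's `VDk(t)` — do not change.  Under the default
`per_time` mode the quantitative variability track is therefore
essentially flat up to sampling noise, and a planted covariance spike
cancels exactly.  Tracking *dispersion over time* requires a fixed
measurement unit, which is what `scatter_mode="pooled"` provides: one
robust scatter from all `N·n` rows, against which a week of inflated
covariance stands out by roughly the spike factor.  The spike-recovery
experiment accordingly runs in pooled mode; the per-time mode remains
the default for the distance matrices themselves, where re-estimating
the scatter per snapshot is what makes each week's comparison robust to
that week's outliers.

## The synthetic generator

`covid_like_spec(seed)` emulates the structural shape of a weekly
multi-source surveillance panel: 25 entities × 59 weeks × 15
quantitative variables in three sources of 6 ("health", level-like,
SD 1–3), 3 ("stringency", index-like, generated unbounded then clipped
to [0, 100], SD 5–10) and 6 ("mobility", percentage-change-like,
SD 5–15).  Mean trajectories are smooth (level + linear trend + one
sinusoid per variable); within-source covariances are random
well-conditioned correlation matrices scaled by the SDs.  Two documented
constants plant recoverable structure: entity index 24 shifted +8 true
SDs in every quantitative variable at all weeks, and a ×4 covariance
spike in "health" at week index 29.  `mixed_type_spec(seed)` is a small
n=10, N=4 fixture with quantitative + binary + categorical blocks so the
Jaccard and Hamming components enter the joint metric.

One integer seed drives everything through deterministically derived
sub-streams, so identical specs give bit-identical panels and files.

What the generator does **not** emulate: epidemic waves, autocorrelated
trajectories, heavy-tailed or skewed marginals, cross-source dependence,
missingness.  Passing tests therefore demonstrate the algebraic and
recovery properties of the method under clean multivariate-normal
panels with planted structure, not performance on real surveillance
data.

## Recovery experiments (problem sizes)

The outlier experiment uses n=25 entities, N=10 times, one quantitative
source of q=6 correlated variables, focal outlier at +8 SD, 200
replicates; recovery means the focal entity attains the maximum
time-averaged φ.  The contaminated variant raises the contaminated
share to 20% of entities by adding a masking cluster shifted 6 SD in
the same direction as the focal outlier — the classic configuration a
non-robust fit absorbs — and compares the robust pipeline's recovery
rate against the identical pipeline with the classical range-normalized
city-block baseline.  (A draft design with random-sign contaminators
was discarded *before* freezing the experiment: under positively
correlated covariance an anti-correlated 6-SD shift is legitimately
more Mahalanobis-extreme than a correlated 8-SD one, so that design
measures metric geometry, not robustness.)  The spike experiment uses
the same panel shape with a ×4 spike at time index 5, 100 replicates,
pooled scatter.  These sizes keep the full suite and the acceptance
script to a few minutes on one CPU while leaving the Monte-Carlo rates
far from their pass thresholds.

## Known limitations

- The MCD subsampling seed is fixed for reproducibility; different
  seeds give (slightly) different scatters on small n.  n=25 with q=6
  is near the small-sample edge for the MCD; the shrinkage fallback
  engages automatically below `n = q + 2`.
- No inferential calibration of the outlier flags: the percentile cut
  is descriptive, and by construction about 10% of entity-weeks exceed
  a per-time 90th-percentile threshold even under homogeneity.
- Time labels are opaque ordered strings — no calendar handling, no
  irregular-spacing adjustment.
- The three-way (entities × variables × time) decomposition of the map
  series is out of scope; maps are computed per time and only aligned.
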