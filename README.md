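# dynagower

Robust Gower distances and dynamic visual analytics for mixed-type panel
data.

When heterogeneous measurements — quantitative counts, 0/1 indicators,
multi-state categories — are observed on the same `n` entities at each of
`N` time points, a natural question is which entities are similar, which
drift apart, and which are systematically far from all the others.
`dynagower` answers this with one squared-distance matrix per time point
and a family of time tracks derived from the whole collection
{D(1), …, D(N)}.  The motivating application is epidemiological country
monitoring (weekly health, policy-stringency and mobility indicators
across EU member states), but nothing in the package is specific to it.

## The method

At each time `t`, variables are split into `m` groups (by type, by
source of information, or both) and each group contributes a matrix of
squared pairwise distances:

- **quantitative** groups: a robust squared Mahalanobis distance,
  `(zi − zj)ᵀ S⁻¹ (zi − zj)`, with `S` the reweighted Minimum Covariance
  Determinant scatter — unlike classical Gower's range-normalized
  city-block part (kept as a comparison baseline), it accounts for
  correlations and resists outliers;
- **binary** groups: `1 − s_J`, with `s_J` Jaccard's similarity
  coefficient (double zeros carry no information);
- **categorical** groups: the Hamming distance (proportion of
  mismatching variables).

Each component `Dk(t)` is rescaled to unit **geometric variability**

    VD = (1 / 2n²) · Σᵢⱼ d²(zi, zj),

a generalization of total variance related to Rao's quadratic entropy;
multiplying squared distances by a constant is only a change of
measurement unit, so the requirement `VDk(t) = 1` is always attainable.
The **joint robust metric** is the sum `D(t) = Σk Dk(t)`; by linearity of
VD it satisfies `VD(t) = m` exactly.

From the collection {D(t)} the package derives:

- **variability tracks** `VDk(t)` per source (from the raw,
  pre-normalization components), optionally min-max rescaled to [0, 1]
  for cross-source comparison;
- **pairwise tracks**, per-time **min/max extremes** with the entity
  pairs achieving them, and a **dynamic box plot** (five-number summary
  of all n(n−1)/2 pairwise distances per time);
- the **proximity function** `φ(z0(t)) = (1/n) Σᵢ d²(z0(t), zi(t)) − VD(t)`,
  whose entity-average equals `VD(t)` identically; entities above the
  per-time 90th percentile of φ are flagged as potential outliers;
- **dynamic MDS maps**: classical principal-coordinates analysis of each
  D(t) (eigendecomposition of the double-centered −½ D(t)), with optional
  orthogonal-Procrustes alignment of consecutive maps and marker sizes
  min-max rescaled to [1, 5] from any quantitative variable.

A seeded synthetic-panel generator produces mixed panels with known
planted structure (location outliers in robust-SD units, per-time
covariance spikes) so that every stage is testable end to end.

## Worked example

```python
import numpy as np
from dynagower import (covid_like_spec, generate_panel, distance_series,
                       proximity_track, flag_outliers, dynamic_mds_series)

panel = generate_panel(covid_like_spec(seed=0))   # 25 entities x 59 weeks x 15 vars
series = distance_series(panel, grouping="by_source", seed=0)
print(len(series.matrices), series.n, series.matrices[0].gv)

track = flag_outliers(proximity_track(series), percentile=90)
mean_phi = track.phi.mean(axis=1)
for i in np.argsort(mean_phi)[::-1][:3]:
    print(track.entities[i], round(mean_phi[i], 3), int(track.flags[i].sum()))
```

prints

```
59 25 3.0
E25 47.308 59
E13 1.487 7
E14 1.315 9
```

i.e. 59 weekly 25×25 joint matrices, each with geometric variability
exactly 3 (three sources: health, stringency, mobility); entity `E25` —
the generator's planted outlier, shifted 8 robust SDs — has a
time-averaged proximity value thirty times larger than anyone else's and
exceeds the 90th-percentile threshold in all 59 weeks, while the runners-up
are flagged only sporadically.  Adding `dynamic_mds_series(series, k=2)`
gives one 25×2 principal-coordinate map per week (at week `t01` the first
two axes carry 63% and 15% of the positive eigenvalue mass).

The same pipeline is available from the shell:

```sh
dynagower simulate --preset covid_like --seed 0 --out run/input
dynagower all --data run/input/panel.csv --meta run/input/meta.yaml \
              --seed 0 --out run/output
```

which writes the per-week distance matrices, the four tidy track CSVs
(`variability.csv`, `extremes.csv`, `boxplot.csv`, `proximity.csv`) with
line-graph PNGs, per-week MDS coordinates and an animation-frame JSON
bundle consumable by any dashboard front end.

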