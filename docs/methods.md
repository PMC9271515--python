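# Methods

## Model

Accessibility follows the Hansen gravity tradition: supply attenuated by an
impedance function of separation, with two deliberate restrictions. First,
**nearest-supply assignment** — a demand point is served only by its closest
trial site, because trial eligibility competition plays out globally rather
than between neighboring catchments, so no local competition term is used.
Second, a **sub-linear distance decay** `d^(-β)` with β = 0.5, the exponent
that describes human mobility at the typical distance between a patient and
a clinical site.

For grid point *i* with population `p_i` in a country with cancer incidence
`r_c` per 100 000:

```
s_i    = p_i · r_c / 100 000              expected patients in the cell
dAI(i) = n_j / max(log s_i, 1) · max(d_ij, floor)^(-β)
```

where *j* is the nearest site and `n_j` its trial count for the year. The
national index is the weighted mean of local values with weights
`w_i = max(log s_i, 1)`, over cells with `s_i > 1`.

The travel-cost variant (tAI) replaces `d_ij` by a user-supplied generalized
cost and assigns each point to its cost-minimizing site with the same
tie-break; everything downstream is unchanged.

### Degenerate inputs and numerical conventions

- **log clamp and exclusion.** `log s_i` is negative for `s_i < 1` and zero
  at 1, which would flip or blow up both the local value and the weight.
  Cells with at most one expected patient are excluded from national
  aggregation (their local value is still computed and mapped); weights for
  included cells are clamped below at 1. This preserves the intended
  "attenuate, don't dominate" role of patient volume without sign
  pathologies. A surface in which every cell is excluded has no defined
  national index and raises, rather than returning 0.
- **distance floor.** A cell hosting a site has `d = 0`. The true average
  distance of a cell's residents to its center is of cell order, so the
  default floor is half the cell diagonal at the cell's latitude,
  `spacing·111.195·sqrt(1 + cos²φ)/2` km (≈ 39 km at 45° for a 0.5° grid);
  a scalar override is available and is what the tests use for closed-form
  arithmetic. Library calls to `local_dai` outside any grid context default
  to a 1 km floor.
- **log base.** Natural log by default; configurable. Within a country every
  relative comparison (ratios, Gini, trends, placement ranking) is invariant
  to the base.
- **tie-breaks.** Equidistant (or equal-cost) sites resolve toward the larger
  `n_trials`, then the lexicographically smaller site id; placement
  candidates resolve toward higher gain, then larger population, then
  smaller point id. All results are therefore reproducible to the byte.
- **zero supply.** A country-year with no sites scores 0 ("no
  accessibility"), and its Gini is reported as explicitly undefined (an
  all-zero vector has no meaningful Lorenz geometry), never as 0.
- **β = 0** is accepted as the no-decay limit (useful for isolating the
  supply and volume terms); negative exponents are rejected.

### Aggregation reading

"Weighted on the logarithm of total population with cancer" admits two
readings: per-point `log s_i` weights, or one country-level log total. Only
the per-point reading yields a well-defined weighted average of local
values, so it is the default; the country-level alternative would rescale
all weights identically and change nothing within a country.

### Cross-border supply

By default the nearest site may lie in another country (patients cross
borders); a `within_country` switch restricts supply to the home country.
During placement optimization only the target country's index is maximized
either way.

## Inequality

Gini over the local values of all populated cells, `G = Σ_ij |x_i − x_j| /
(2 n² x̄)`, computed in O(n log n) from the sorted vector and cross-checked
in the tests against the O(n²) pairwise definition. Unweighted by default —
each cell is one unit of territory, matching the "distribution of
accessibility" reading — with a population-weighted option. Zero-valued
(unserved) cells are included: they are precisely the inequality being
measured. The global Gini pools grid cells across countries, so one
machinery serves both scopes; pooling national indices instead is available
as an option. Lorenz curves are exported alongside, and `1 − 2·area` under
the discrete Lorenz curve reproduces the Gini exactly with trapezoidal area.

## Trend statistics

- **Increments**: `100·(x_t − x_base)/x_base`; undefined when the base-year
  value is 0 (raised, not silently dropped).
- **AUC**: trapezoidal, over year index with unit spacing. Only AUC *ratios*
  are interpreted (accessibility-AUC / trials-AUC < 1 means access grows
  slower than trial counts), and ratios are invariant to the spacing choice.
- **Mann–Kendall**: S is the sign-sum over ordered pairs; τ is the
  tie-corrected τ-b (annual values can tie at 0). For tie-free series with
  n ≤ 10 the p-value is exact, from the permutation null computed via the
  inversion-count (Mahonian) distribution; otherwise the normal
  approximation with tie-corrected variance and ±1 continuity correction.
  The exact rejection probability of the p ≤ 0.05 rule at n = 15 is 4.63%,
  so the test is calibrated, slightly conservative. Trends are flagged
  significant at p ≤ 0.05, two-sided; no multiple-testing correction is
  applied across countries by default (a Benjamini–Hochberg option exists).
- **Pearson correlation** delegates to scipy.

## Placement optimization

Candidates are the populated grid cells of the target country (optionally
pruned to the top-N by population; unpopulated cells are dominated — they
capture no demand and carry no weight). Evaluating a candidate re-assigns
only the points the hypothetical site actually wins under the distance
tie-break, which agrees *exactly* (bitwise) with a full surface
recomputation — verified per-instance in the tests. Placement is greedy and
sequential: the first location is committed before the second is searched,
matching the one-more-location planning question; a joint exhaustive search
over candidate pairs is retained as a test oracle and for gap measurement on
small instances. At k = 1 greedy *is* exhaustive. The default size of a new
site is the median trial count of the country's existing sites that year.

Because supply is nearest-only, adding a site is not monotone pointwise: a
1-trial site opening at 25 km captures a point previously served by a
10-trial site at 100 km and cuts its local value to 0.2× (the ratio
`(1/√25)/(10/√100)` is weight-independent). The packaged demonstration
constructs and verifies exactly this configuration.

## Synthetic data

Blueprints generate countries on a uniform lattice: `uniform`, `gradient`,
or `urban_poles` population (n poles with geometrically decreasing masses
holding a configurable share, optionally equal-mass, optional Gaussian
dispersion), an optional 0/1 mask for non-rectangular territory, and a site
policy per year — `concentrated` (≥ the configured share, default 85%, of
the year's trials at the most populous cell; tail hosts open only while
that share is preserved), `proportional` (largest-remainder allocation by
host population) or `random`. Everything is a pure function of
(blueprint, seed). Populations are per-cell counts in index space; no
latitude cell-area correction is applied when spreading population, unlike
real gridded-population rasters whose cells shrink poleward — synthetic
populations are specified per cell, so no correction is wanted.

Cost matrices: `distance` (haversine) or `distance_plus_congestion`, which
inflates every trip leaving cell *i* by `1 + γ·rank_i` with `rank_i` the
cell's population percentile. The factor is per-origin, so each point's
ranking over sites — hence its serving site — is preserved and
`tAI(i) = dAI(i)/(1+γ·rank_i)^β ≤ dAI(i)` pointwise, making the
travel-cost-never-exceeds-distance comparison hold for every input rather
than on average.

Trend panels encode growth regimes with known ground truth:

- `flat` — fixed hosts, i.i.d. `1 + Poisson` counts per site-year (default
  ≈ 60 trials/year per country, the scale of a stable mid-size country; at
  that scale the index series is effectively tie-free, so the nominal level
  of the trend test is meaningful under this null);
- `linear` / `accelerating` — noise-free counts growing linearly /
  quadratically at every host, hence strictly increasing index (τ = 1);
- `decoupled` — all growth is committed to one dominant hub. The national
  index is linear in each site's count with coefficient
  `q_j = Σ_{i∈catchment j} max(d,floor)^(-β)` (the log weights cancel), so
  the access-AUC/trials-AUC ratio equals `q_hub·T₀ / Σ_j q_j n_j(0)`, which
  is < 1 **iff** the hub has the strictly smallest per-trial coefficient.
  The generator therefore probes the baseline geometry, designates the
  argmin-q site as the hub and gives it the largest initial count; a
  degenerate geometry with all-equal coefficients raises instead of
  silently producing an unprovable panel. This makes "accessibility lags
  trial counts" a theorem of the construction, true in every replicate.

## What the synthetic tests do and do not show

Passing tests demonstrate internal correctness (formula fidelity, oracle
equivalence, optimality, calibration) and that the pipeline recovers the
mechanisms the generators encode: concentration of trials raises
within-country inequality, hub-concentrated growth decouples trial counts
from accessibility, congested travel costs depress the index relative to
plain distance. They do not validate magnitudes on real registries: real
trial-location data carry reporting and geocoding biases, real population
rasters have latitude-dependent cell areas, and real travel costs are not a
monotone transform of distance everywhere. Analyses of real data should
treat the synthetic results as checks of machinery, not as effect-size
anchors.

## Problem sizes

Defaults keep every stage interactive on one core: fixture countries have
56–117 cells, the optimizer oracle instances ≤ 100 candidates (joint k = 2
search ≤ 30), the type-I panel 2000 replicates of a 15-year series over a
25-cell country. The full suite runs in about a minute; the acceptance
script in about 15 s.
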