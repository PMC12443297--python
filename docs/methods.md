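# Methods

## The access model

The package measures geographic (spatial) access to healthcare providers
with the enhanced two-step floating catchment area method. The method's
premise is that supply and demand interact within a travel-time catchment:
step one allocates each provider site's capacity over the decay-weighted
population that can reach it, yielding a per-site provider-to-population
ratio `R_j = S_j / Σ_k P_k W(d_kj)`; step two sums the decay-weighted
ratios reachable from each area, `A_i = 100000 · Σ_j R_j W(d_ij)`. The same
area-to-site travel-time matrix serves both steps (patient-travel
direction), which yields the conservation identity
`Σ_i P_i A_i / 100000 = Σ_j S_j` over sites whose catchment contains
population — the package's strongest internal correctness check, tested to
1e-9 relative tolerance and exercised against an exact-rational double-loop
oracle.

Assumptions worth keeping in mind: capacity is one unit per
provider-location record (a provider with a hospital and a clinic site
contributes at both — deliberate double counting, since there is no data on
how clinicians split time across sites); demand is residential population
at area centroids; willingness to travel is a step function of travel time
with a hard 30-minute cutoff.

### Numerical choices

* Decay zones are half-open `(lower, upper]` with 0 in the first zone, so a
  travel time exactly on a cut point maps to exactly one weight and results
  are bit-stable.
* Catchment sums use correctly rounded summation (`math.fsum`), making
  access values independent of the accumulation order and exactly
  reproducible by any correctly rounded reimplementation.
* A site with no population in its catchment gets `R_j = 0` (not infinity):
  provider-to-population semantics, and surfaces stay finite.
* Unreachable pairs are `+inf` in matrices, never a sentinel number; the
  decay weight of `+inf` is 0.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `zone_bounds` | 10, 20, 30 min | travel-time zone cut points; last = catchment `D0` |
| `zone_weights` | 1.00, 0.68, 0.22 | step decay per zone (canonical Gaussian-derived values from the method's literature; configurable) |
| `scale` | 100 000 | access expressed as providers per 100k population |

## Travel model

Car and walk times are Dijkstra shortest paths on abstract mode networks
(minutes on edges); origins/destinations snap to the nearest node within a
snap radius (default 1 distance unit ≈ 1 km at toy scale) and are
unreachable beyond it, with a logged warning rather than an exception.
Transit time is the minimum over single-line (boarding, alighting) stop
pairs of *walk access + headway/2 + in-vehicle + walk egress*, compared
against pure walking, so transit never exceeds the walk time. The
half-headway term is the expected wait under uniformly random arrivals;
schedule effects, transfers and congestion are out of scope (transfers
would require relaxing the exhaustive-enumeration oracle that currently
verifies the router). The walking cap on access/egress legs defaults to
15 minutes and applies to both legs.

## The synthetic-region generator

Downstream code is tested on generated regions that emulate the structure
of U.S. access data rather than any real geography. Areas are scattered on
a disk whose radial coordinate is in car-minutes from a single core
(default radius 60 car-minutes, 400 areas); rural/urban strata follow
distance-from-core quantiles (35% metropolitan by default, remainder split
evenly into micropolitan / small town / rural) as a stand-in for
commuting-based rural-urban codes. Expected population declines
exponentially with distance from the core (≈5100 near the core to ≈900 at
the edge, Poisson-sampled); about 45% of residents commute, split
multinomially by stratum-specific mode-share profiles (car share rising
from 0.80 metropolitan to 0.96 rural, transit falling from 0.12 to 0.01).
Providers are placed with Pareto-like radial concentration (`r = R·U^c`,
default `c = 3`), with ~8% of providers given a second practice location to
mirror retained duplicates. Between periods, provider counts grow 15% for
the generalist class and 50% for the specialist class (matching the
direction and rough magnitude of observed national primary-vs-specialty
divergence), with growth placed twice as core-concentrated as the base —
urban-favouring change. Deprivation quartiles are pure noise, deliberately
uncorrelated with access, because the empirical pattern across deprivation
strata is weak and the default fixture should not bake a correlation in.

Travel matrices are generated directly from the geometry: car minutes equal
planar distance, walking is 12× slower, transit is walk-to-stop (2–8 min
per endpoint) + half of a 12-minute headway + in-vehicle at half car speed,
finite only when both endpoints lie within the transit coverage radius
(default 20 car-minutes) of the core.

`inject_zero_inflation` forces exact structural zeros: it makes every site
of one classification unreachable from a chosen fraction of rural areas
(stratum set configurable), so specialist access is exactly 0 there in
every mode and period — the "excess zeros" regime that motivates the
zero-inflated test.

What the generator does **not** emulate: real street/transit topology
(matrices come from geometry, not networks), multiple urban cores,
in-vehicle transit ever beating the car (so synthetic composites sit at or
below car access, unlike dense real cores where transit raises the
composite — that pattern is exercised by constructed fixtures instead),
temporal provider attrition, and any correlation between deprivation and
access. Passing tests therefore demonstrate the machinery's correctness and
directional sensitivity, not calibration to any real region.

## Disparity statistics

Stratified summaries report per-stratum medians and differences versus a
reference stratum (metropolitan for rural/urban, first quartile for
deprivation), with the difference signed as *reference minus stratum* so a
positive difference reads "worse off than the reference". Percent change is
computed per area, `100·(A_t2 − A_t1)/A_t1`, and summarised by stratum
medians: the per-area form is needed for a distribution on which rank tests
can run, `0 → 0` is defined as 0% so all-zero strata are representable, and
`0 → positive` has no defined percent change — such areas are excluded from
medians and counted in the report manifest.

Two-group contrasts use the two-sided Wilcoxon–Mann–Whitney rank-sum test:
exact null distribution when the pooled sample is ≤ 12 without ties
(verified against exhaustive enumeration of all assignments), otherwise the
normal approximation with midrank ties and continuity correction. When
either group's zero fraction exceeds a threshold (default 0.25, the table
marker being a judgement call in the source material), the contrast
switches to a two-part zero-inflated rank-sum test: a pooled two-proportion
z on zero frequencies plus a rank-sum z on the nonzero values, combined as
the sum of squared informative z's against chi-square with one degree of
freedom per informative part. Degenerate cases fall back gracefully: one
informative part gives a 1-df test; none (both groups all zero) gives p = 1
with a degeneracy flag. The positive-part z omits the continuity correction
(squaring a corrected z would bias the chi-square combination). Under a
shared 60%-zero lognormal null (n = 100 per group, 10 000 replicates) the
empirical type-I error at α = 0.05 is ≈ 0.050. No multiple-testing
adjustment is applied; the report gives raw p-values per contrast.

A subtlety of 2SFCA worth stating: increasing one area's travel time to a
site lowers that area's access but *raises* access elsewhere in the site's
catchment, because a fixed capacity is redistributed over less competing
demand. Monotonicity holds in supply (adding sites never lowers any area)
and for the directly affected area, not globally.

## Problem sizes

Default test and reproduction runs use regions of 60–480 areas with a few
hundred provider-site records, 200 random oracle instances of ≤ 20 areas ×
≤ 10 sites, 10 000 replicates for test calibration, and 10 000 draws for
convexity checks — sizes chosen so the full suite re-derives every property
from scratch in well under a minute per check on a single core.

## Known limitations

* Single-boarding transit, no transfers or schedules; headway/2 wait.
* Areas are points; no areal interpolation or polygon demand weighting.
* Capacity is count-based; no FTE or panel-size adjustment.
* The zero-excess threshold for test switching is a convention (0.25),
  configurable but not estimated.
* GeoJSON export is plain FeatureCollections in the input's planar
  coordinates; no CRS reprojection.
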