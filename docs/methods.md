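# Methods

`serisk` implements a place-based pipeline for locating potential
superspreading environments in a city. It combines four data sources — a
trip-based travel-diary survey, point locations of six facility types
(bars, cinemas, gyms/fitness centers, places of worship, public libraries,
shopping malls), census polygons with population, and a road network — and
produces, per city: per-person daily mobility volumes, a facility-type-level
association between spatial agglomeration and visitor mobility, a four-class
potential-spatial-risk (PSR) label per facility, and a weighted
kernel-density risk surface with a top-quarter high-risk mask.

All computation happens in one projected planar coordinate system with
kilometre units; readers refuse raw longitude/latitude so that space-time
volumes are always in km²·h.

## Space-time prism (STP) volumes

A person's daily mobility is the sum of travel prisms and activity prisms
over their one-day diary.

* **Travel prism** = area of the minimum bounding 2-D activity space of the
  trip's shortest network route × the recorded travel time (arrive −
  depart). The bounding space is taken as the convex hull of the route
  vertices. Travel time comes from the diary, not from network speeds,
  because surveys record it directly.
* **Degenerate routes.** A straight out-and-back trip has a zero-area hull;
  such routes fall back to the area of an ε-buffer corridor around the
  polyline (ε = 0.01 km, configurable), so no moving trip contributes
  exactly zero.
* **Activity prism** = disc footprint πr² at the destination × dwell
  duration, with r = 0.1 km by default. Dwells are the inter-trip gaps at
  each destination; the final dwell is closed at 24:00 unless the
  destination is home. Dwells at home contribute nothing — the measure is
  out-of-home activity.
* **Routing.** Endpoints snap to the nearest network node; the node path
  minimises edge length. Paths are served from a cached all-pairs
  predecessor matrix (scipy.sparse.csgraph) with nodes in canonical spatial
  order, so route tie-breaks do not depend on node labelling and a written
  bundle reruns bit-identically.

Persons in the expansion-weighted top 25% of total volume are flagged
"large STP" (highly mobile).

### Weighted quantiles

Survey expansion factors enter every quantile as frequency weights. The
convention: sort values, normalise weights by their mean, and interpolate
linearly on cumulative-weight positions p_i = W'_{i−1}/(n−1). With equal
weights this reduces *exactly* to numpy's default linear quantile (so the
documented example — totals 1…8, top quarter ⇒ threshold 6.25 — holds), and
rescaling all weights leaves every threshold unchanged. Thresholds are
inclusive (≥), so ties are flagged.

## Visitor matching

A person visits a PoI when some trip of theirs ends in the census unit
containing the PoI **and** the trip purpose maps to the facility type under
the fixed map {eat_drink→bar, leisure→cinema, exercise→gym,
worship→worship, study→library, shop→mall}. The "spatial unit" is
identified with the census unit — the only polygon partition in the data
model. Points on shared unit boundaries belong to the unit whose identifier
sorts first, a deterministic tie rule independent of the geometry backend.

Per-PoI **visitor mobility** is the expansion-weighted mean daily STP of
matched visitors, compared within facility type: a PoI is "high visitor
mobility" when its mean is at or above the type's 75th percentile. The
comparison pool is type-wise (not city-wide) because visitor volumes and
mobility levels differ structurally between, say, malls and libraries.

## Agglomeration and the A/B/C association

Per facility type, Thiessen (Voronoi) cells of the type's PoIs are clipped
to the city boundary; cell areas sum to the city area (checked at 1e-6
relative). The quarter of PoIs with the smallest cells is "high
agglomeration" (12.5% under the stricter robustness setting; the flag sets
are nested by construction — sort by area then id, take the first ⌈q·n⌉).
Coincident PoIs are jittered by ~1e-6 km with a seeded stream because a
Voronoi diagram of duplicate generators is undefined.

The agglomeration–mobility association per type is an independent-samples
difference-of-means test of visitor daily STP between the high- and
low-agglomeration strata. The unit of analysis is the person-visit: a
person matched to PoIs in both strata contributes to both. Expansion
factors act as frequency weights; degrees of freedom use effective sample
sizes n_eff = (Σw)²/Σw² with Satterthwaite's formula. Welch's
unequal-variance form is the default — visitor STP variances differ wildly
between strata in this kind of data — with the pooled Student form
available via config. Outcomes: **A** (agglomeration ↔ larger STP), **B**
(lack of agglomeration ↔ larger STP), **C** (no significant difference at
α = 0.05). No multiple-testing correction is applied across the six types
by default (a Bonferroni switch exists, off by default).

## PSR classes

Each PoI is classified from (type group, own agglomeration flag, visitor
mobility flag, population-density flag), where "high population density"
means the PoI's census unit is in the top 25% of unit densities. The
ordered decision table:

1. group A ∧ high agglomeration → **Class 1**
2. group B ∧ low agglomeration → **Class 1**
3. low agglomeration ∧ low mobility ∧ high density → **Class 2**
4. low agglomeration ∧ low mobility ∧ low density → **Class 4**
5. otherwise → **Class 3**

Rule order resolves a genuine ambiguity: a group-B PoI with low
agglomeration and low mobility stays Class 1 — for those types the lack of
agglomeration is itself the risk factor. Group-C types never reach
Class 1. The table is total and exclusive over all 24 combinations and is
isolated in one function so alternative readings are one-line swaps.

## Risk surface

Each PoI contributes a quartic (biweight) kernel K(u) = (3/π)(1−u²)²
truncated at one bandwidth, scaled by PSR-class weight × activity weight.
The class weights are exponential — 1000/100/10/1 for classes 1–4 — and the
activity weights rank the riskiness of what people do there: 5 for bars,
cinemas and gyms, 4 for worship, 3 for malls, 2 for libraries. The two
factors combine multiplicatively (the natural reading when both are
declared as weights). Defaults: bandwidth 1 km, cell 0.1 km, both
configurable; the quartic kernel is the common choice in planning GIS.

Density over in-boundary cells is displayed in eight equal-count quantile
classes (ties to the lower octile) and cells at or above the 75th
percentile form the high-risk mask; both are rank statistics, invariant
under monotone transforms of density. A density-only surface (all weights
equal) is computed alongside as the traditional comparison map. Population
density enters only through the Class-2 assignment by default; an optional
mode additionally multiplies each PoI's weight by its unit's
min-max-normalised density rescaled to [1, 2].

Rasters are written as ESRI ASCII grids (plain text) with a GeoJSON
polygon layer for the dissolved high-risk mask and a rendered octile map.

## Synthetic city generator

Municipal travel diaries are license-restricted, so the package ships a
generator that emulates their trip-based structure with plantable ground
truth. Default study conditions (chosen once, as a realistic mid-size
city):

* 14×14 km boundary, 0.5 km grid street network, 140 Voronoi census units
  with log-normal populations (μ = 8, σ = 0.6 on the log scale).
* Homes and facilities occupy the built-up interior (homes ≥ 3.5 km,
  facilities ≥ 2.5 km from the edge); the fringe band is empty. This keeps
  daily excursions from being systematically clipped by the map edge.
* Facility counts {bar 48, worship 36, gym 30, cinema 16, library 16,
  mall 12}. Bars are **mixed**: a quarter in tight districts (Matérn
  clusters, parents + 0.3 km Gaussian offsets) and the rest standalone —
  a type can only show an agglomeration contrast if both states exist.
  The other five types are dispersed by sequential inhibition with minimum
  spacing 0.7·√(A/n), which also keeps opposite-stratum neighbours from
  sharing one census unit.
* 3,000 surveyed persons, in the range of real travel-diary samples. Each
  person gets: a home; a facility-type drawn uniformly; one PoI of that
  type by a gravity rule (probability ∝ exp(−distance/1 km), so nearby
  facilities and districts of them attract more visitors); three work
  excursions at 1.5/2.0/2.5 × their mobility scale in off-axis directions;
  a return home. 4–6 trips per day with consistent, non-overlapping times
  and a positive log-normal expansion factor.
* Person mobility scale: winsorized log-normal, median 1.1 km, σ = 0.35 on
  the log scale, z capped at +2 (the cap sits at the same z for everyone,
  so the planted effect survives in the upper tail). The resulting daily
  STP distribution is heavy-tailed (std ≳ mean), as survey STP tables show.
* **Planted effect.** Persons whose anchor PoI is in the risky
  agglomeration state for its type — high agglomeration for bars, low for
  the others — get +d·σ on their log mobility scale (d = 1 by default).
  The effect is planted on the mobility scale, not on STP, so recovering it
  exercises routing, prisms, matching and the weighted test end to end.
  The facility choice itself never depends on the mobility scale, so
  cohort membership and the boost are not circular.
* Seeding is hierarchical (numpy SeedSequence spawns one child per
  sub-generator), so changing facility counts does not perturb diaries.

Ground truth records the expected group per type (A for bars, B otherwise;
all C when d = 0), the risky PoI set, and the implied Class-1 set.

**What the generator does not emulate:** multi-day diaries, mode choice and
congestion, GPS-trace geometry, correlated household travel, non-uniform
departure-time peaks, and real cities' irregular street networks. Passing
recovery tests therefore shows the pipeline recovers a planted
agglomeration–mobility association under survey-like sampling noise — not
that any particular real city exhibits one.

## Numerical choices and degenerate inputs

* Quantile thresholds are inclusive; all-equal inputs flag everyone.
* Octile ties go to the lower octile; a constant surface is all octile 1
  and, with every cell at the threshold, all high-risk.
* Zero-variance strata with equal means give t = 0, p = 1; with unequal
  means, p = 0.
* A facility type with fewer than two visitors in a stratum cannot be
  tested and is assigned Group C with p = NaN (logged); the low-level test
  function itself raises.
* Overnight trips are clipped at 24 h with a logged warning (diaries are
  one-day).
* Trips CSV I/O uses %.17g and round-trip float parsing, so a written
  bundle reruns bit-identically.

## Problem sizes used in checks

The shipped test-suite and the acceptance script run the default scenario
over 20 seeds (~3,000 persons, ~160 PoIs each), 1,000 direct null
replicates at n = 500 for test calibration, 100 generator replicates at
n = 500 for the null-transmission check, a 10⁶-sample Monte-Carlo
integration for Thiessen areas, 300–1,000 random routes against a
brute-force hull oracle, and double-loop kernel sums at sampled cells.

## Known limitations

* The "minimum bounding 2-D activity space" is read as the convex hull;
  other readings (minimum bounding rectangle/circle) would scale volumes by
  a bounded factor but preserve ranks.
* Whether Class 1 additionally requires high visitor mobility is an open
  reading of the class definitions; the implemented table takes the
  group-B Class-1 wording literally (see above).
* Unit-level visitor matching cannot distinguish two same-type facilities
  in one census unit; both inherit the same visitors.
* The kernel bandwidth and cell size are conventions, not estimates; the
  high-risk mask is a rank statistic, so moderate bandwidth changes move
  its boundary smoothly.
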