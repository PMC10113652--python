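# serisk — spatial risk mapping of superspreading environments

`serisk` identifies urban places likely to act as *superspreading
environments* — facilities whose visitor volume, visitor mobility, setting
and activities jointly favour disproportionate onward transmission — from
four standard inputs: a trip-based travel-diary survey, point locations of
six facility types (bars, cinemas, gyms & fitness centers, places of
worship, public libraries, shopping malls), census polygons with
population, and a road network. It is written for epidemiologists, urban
analysts and public-health teams designing place-based non-pharmaceutical
interventions (closing *selected* facilities instead of city-wide
lockdowns).

## The method

1. **Travel intensity (space-time prisms).** For each surveyed person, each
   trip contributes a travel prism — the area of the convex hull of its
   shortest network route times the travel time — and each out-of-home stay
   contributes an activity prism (disc footprint πr² × dwell time). Their
   daily sum (km²·h) measures how much space-time a person sweeps; the
   expansion-weighted top 25% are "large STP" (highly mobile).
2. **Facility agglomeration (Thiessen polygons).** Per facility type, each
   PoI gets its Voronoi cell area clipped to the city; the smallest-cell
   quarter is "high agglomeration".
3. **Association test.** Per type, an expansion-weighted Welch *t*-test
   compares daily STP of visitors to high- vs low-agglomeration
   facilities: Group **A** (agglomeration attracts mobile visitors),
   **B** (lack of agglomeration does), or **C** (no difference).
4. **Potential spatial risk (PSR).** Each PoI gets class 1–4 from its
   type's group, its agglomeration flag, its visitors' mobility flag, and
   whether its census unit is in the top population-density quarter
   (Class 1 = riskiest).
5. **SE-risk surface.** A quartic kernel density of PoIs weighted by
   PSR class (1000/100/10/1) × activity riskiness (bars/cinemas/gyms 5,
   worship 4, malls 3, libraries 2), shown in octiles; cells ≥ the 75th
   percentile form the high-risk mask. A density-only surface (equal
   weights) is produced for comparison.

Because real travel diaries are license-restricted, the package ships a
synthetic-city generator (`serisk.synthetic_city`) that emulates their
trip-based structure and plants a known agglomeration–mobility effect, so
every stage is testable end to end. See `docs/methods.md` for the model,
parameter defaults and the generator's scope.

## Worked example

```python
import serisk
from serisk.synthetic_city import generate_scenario

bundle, truth = generate_scenario(seed=0)   # synthetic city, planted effect
result = serisk.run_pipeline(bundle)

print(result.summary.round(2))
for g in result.groups:
    print(g.facility_type, g.group, round(g.p_value, 4))
```

prints the descriptive block (per facility type: facilities visited, the
expansion-weighted mean and std of visitor daily STP in km²·h, distinct
visitors, and the expansion-weighted population they represent):

```
         n_pois  mean_stp  std_stp  n_samples  expanded_population
bar          48      4.87     5.70        516               799.78
cinema       16      6.11     8.28        523               810.31
gym          30      6.98     8.92        509               789.08
worship      36      6.16     7.79        466               723.90
library      16      6.39     7.06        492               755.48
mall         12      5.91     7.00        494               774.72
total       158      6.07     7.55       3000              4653.28
```

and the per-type association outcomes:

```
bar      A  mean_high=   7.34  mean_low=   4.51  t=  3.76  p=0.0003
cinema   B  mean_high=   3.71  mean_low=   8.26  t= -6.46  p=0.0000
gym      B  mean_high=   3.81  mean_low=   8.39  t= -6.95  p=0.0000
library  B  mean_high=   3.97  mean_low=   7.67  t= -6.10  p=0.0000
mall     B  mean_high=   3.76  mean_low=   7.68  t= -6.53  p=0.0000
worship  B  mean_high=   3.76  mean_low=   7.22  t= -5.42  p=0.0000
```

Agglomerated bars attract significantly more mobile patrons (Group A);
for every other facility type the *standalone* facilities do (Group B) —
exactly the structure the generator planted. Downstream,
`result.labels` carries the PSR class per facility (here 94 Class-1, 7
Class-2, 31 Class-3, 26 Class-4) and `result.surface.high_risk` the
top-quarter risk mask (4,900 of 19,600 cells).

## Command line

```bash
serisk simulate --seed 0 --out city/          # synthetic bundle + truth
serisk run --city city/ --out out/            # all stages, every intermediate
serisk robustness --city city/ --out out/     # 25% vs 12.5% threshold rerun
```

`stp`, `classify` and `surface` run individual stages; all subcommands
accept `--config` (YAML key:value) and `--seed`. Outputs are
stage-numbered CSV/GeoJSON/ASCII-grid files plus a rendered octile map.

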