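# ugsim

A spatially explicit agent-based model (ABM) of socio-economic inequality in
urban green space (UGS) visiting, together with a spatial-microsimulation
(MSM) baseline for cross-model comparison.

Visiting parks benefits physical and mental health, yet visit rates are
strongly patterned by socio-economic status (SES) and differ between cities.
`ugsim` implements the *social integration hypothesis* as a simulation: the
primary driver of the decision to (re)visit a green space is an assessment
of **who else is there**. It is aimed at researchers in urban public health
and computational social science who want to probe when inter-group
preferences, residential segregation, walkability and park quality are
sufficient to generate the observed inequality patterns.

## The model

Agents (residents aged 16–75, at 1/10 scale) carry an SES grade
*c* ∈ {AB, C1, C2, DE}, age *y*, a home location, dog ownership *dg*, a
daily visit propensity *p*, and an ordered list *g* of green spaces whose
size-proportional catchment reaches their home. Each simulated day (1460
days = 4 years by default) agent *i* visits the first space in *g* with
probability

&nbsp;&nbsp;&nbsp;&nbsp;*p*ᵢ × *w* × *s*

where *w* ∈ {0.5, 0.66, 1, 2} is the home zone's walkability-quartile
factor and *s* ∈ (0, 1] the city's annual-sunshine factor. Visitors then
evaluate a sample of co-visitors against Schelling-style tolerance
thresholds:

- **homophilic** agents (all of AB/C1, and a share of C2/DE) are
  dissatisfied when the proportion of the *other* grade pair exceeds their
  threshold *t*;
- **heterophilic** agents (a fraction *h* of C2/DE) are satisfied only when
  the proportion of higher-SES co-visitors reaches their threshold *ht*.

Satisfaction updates the propensity multiplicatively,
*p*ᵢ,d+1 = *p*ᵢ,d ± *a*·*p*ᵢ,d with *a* = 0.25, and reorders the park list
(an unsatisfying space is demoted to the tail). Dog owners keep a floor of
*p* = 0.33. A pattern of inequality *emerges* when three conditions hold
jointly across cities: med(v_AB) > med(v_DE) within every city, the
reference (Edinburgh-like) city has the highest total visits V, and the
lowest AB/DE inequality ratio.

The package also ships:

- a **synthetic city generator** (zone grid with tunable SES shares,
  spatially blocked segregation, walkability–SES correlation, log-normal
  park sizes) plus GeoJSON I/O for custom layouts;
- the **parameter sweep** over (t, ht, h) — the default grid is the 100-cell
  5×5×4 design — with seeded replicates, emergence maps, the environmental
  scenario ladder (social-only → +walkability → +quality) and the
  randomized-residence quasi-null;
- the **MSM baseline**: iterative proportional fitting (IPF) of a survey to
  zone marginals on age band, gender, ethnicity and SES, unbiased
  truncate-replicate-sample integerisation, zone behaviour medians, and the
  Pearson comparison of ABM vs MSM zone medians.

## Worked example

```python
from ugsim import (two_city_suite, build_suite_layouts, run_city,
                   check_emergence, DemogConfig, SimParams)

layouts = build_suite_layouts(two_city_suite())   # Edinburgh-like vs Glasgow-like
demog = DemogConfig()                             # 1/10 scale, 24% dog owners
params = SimParams(t_mu=0.5, ht_mu=0.5, h=0.66, scenario="social_only")

results = {}
for name, layout in layouts.items():
    res, _, _ = run_city(layout, demog, params, seed=11 + len(results))
    results[name] = res
    print(name, res.median_visits_by_ses, res.total_visits,
          round(res.inequality_ab_de, 2))
print(check_emergence(results, reference_city="edleith"))
```

prints

```
edleith {'AB': 1122.0, 'C1': 1131.0, 'C2': 1100.0, 'DE': 1062.0} 1862404 1.06
glasfork {'AB': 839.0, 'C1': 500.0, 'C2': 643.0, 'DE': 399.0} 1132535 2.1
(True, {'gradient': True, 'reference_total': True, 'reference_inequality': True})
```

Over four simulated years the Edinburgh-like city (55% AB+C1, low
segregation) sustains high visiting in every grade and low AB/DE inequality
(1.06), while the Glasgow-like city (35% AB+C1, strongly segregated) shows a
steep gradient (2.10) and about 40% fewer total visits — all three
emergence conditions hold with the Edinburgh-like city as reference.

The same experiments are available from the shell:

```bash
ugsim build-city city_suite.yaml cities/      # suite: default → 4 GeoJSON files
ugsim simulate cities/edleith.geojson out/ --days 1460 --scenario social_only
ugsim sweep cities/ sweep_out/ --replicates 10 --reference edleith
ugsim msm survey.csv marginals.csv msm_out/
ugsim compare abm_medians.csv msm_out/msm_zone_medians.csv paired.csv
```

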