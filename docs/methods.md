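# Methods

## Model overview

`ugsim` simulates daily decisions to visit urban green spaces (UGS) in a
stylised city. The behavioural core is a Schelling-type tolerance
mechanism: agents react to the socio-economic composition of the co-visitors
they meet, and their propensity to visit adapts multiplicatively. The model
is a *plausibility probe*, not a forecasting tool: its purpose is to map the
parameter region in which intra-city SES gradients and inter-city
differences in visiting jointly emerge, and to measure how environmental
modifiers (walkability, park quality) and residential segregation move that
region.

### Agents

Each agent holds: SES grade c ∈ {AB, C1, C2, DE}; age y ∈ [16, 75]; a home
point inside its zone; dog ownership dg (24% in every grade by default); a
visit propensity p ∈ [1e-4, 1]; an ordered accessible-park list g; and
exactly one active tolerance threshold — t for homophilic agents, ht for
heterophilic ones. Only C2/DE agents can be heterophilic; a fraction h of
them is, drawn per agent.

The initial propensity is N(0.07, 0.025) truncated to [0.001, 0.5]
(0.07 ≈ one visit per 14 days), multiplied by an age factor declining
linearly from 1.0 at 16 to 0.5 at 75, halved if the nearest park is beyond
1600 m (≈ 20-minute walk), and floored at 0.33 for dog owners. The age
gradient's linear shape and its endpoint are modelling choices; the survey
gradient that motivates it is not publicly tabulated. The dog floor applies
to the base propensity p, not to the product p·w·s, so a dog owner in a
low-walkability zone can have an effective daily probability below 0.33;
we read the floor as an attribute of the propensity.

### Daily step

1. Every agent visits with probability min(1, p·w·s). w is the zone's
   walkability-quartile factor (0.5 / 0.66 / 1 / 2 for Q1–Q4) unless the
   scenario is `social_only`, which forces w = 1; s is the city's sunshine
   factor.
2. A visitor walks its park list in order. Under the `quality` scenario each
   low-quality park is skipped with a per-grade probability (defaults:
   AB/C1 0.5, C2/DE 0.2 — higher SES avoids poorly maintained spaces more);
   if every listed park is skipped there is no visit and no update.
3. After *all* visits of the day are resolved, each visitor evaluates the
   end-of-day roster of its park, excluding itself and sampling at most 30
   co-visitors (hypergeometric subsample of the grade tallies). A
   homophilic agent is dissatisfied iff the other-pair proportion strictly
   exceeds t ("exceeds" → strict); a heterophilic agent is satisfied iff
   the AB+C1 proportion is at least ht ("minimum acceptable" → inclusive).
   An empty park is neutral: the model defines reactions only to observed
   others.
4. Satisfied: p ← min(1, p(1+a)) and the park moves to (or stays at) the
   head of the list, binding the agent to the same space. Dissatisfied:
   p ← p(1−a) and the park is demoted to the tail. a = 0.25. Dog owners are
   re-floored; p is clamped to [1e-4, 1] so agents remain recoverable.
5. Every 90 days, localized social influence: the reference group is
   same-zone, same-grade agents within ±10 years of age (≥ 5 members,
   otherwise no effect). If an agent's visit rate r over the period is
   below half or above double the group's median rate m, its propensity
   moves toward m by a nudge fraction (default 0.1): p ← p + 0.1(m − p).
   The period, band and nudge are configurable; the original procedure is
   described only qualitatively, so this re-specification is a default, not
   ground truth.

Because evaluation happens against end-of-day rosters (two-phase), the
daily outcome is independent of agent iteration order; the vectorised
kernel therefore draws all visit Bernoullis at once. The per-agent rules
are also exposed as scalar functions, and a no-feedback binomial oracle
ties the two paths together in the tests.

### Emergence conditions

For a run over a set of cities with a designated reference (the
Edinburgh analogue), the inequality pattern *emerges* when, on
replicate-averaged medians: (1) med(v_AB) > med(v_DE) in every city;
(2) total visits V are strictly highest in the reference; (3) the
AB/DE median ratio is strictly lowest in the reference. A zero DE median
makes the ratio +∞: in a comparison city that counts in the reference's
favour, in the reference it fails condition 3. Replicate averaging averages
the per-grade medians first and recomputes the ratio from the averages;
pooling agents across replicates would be the alternative reading, and
averaging medians was chosen as the more direct one.

## Synthetic cities

Real census, green-space and survey inputs are deliberately out of scope;
the generator emulates their statistical structure:

- **Zones**: a square grid (default 16 zones of 1250 residents over a
  6 km extent ≈ 20 000 residents, simulated as 2000 agents at 1/10 scale).
  Zone SES shares are a convex mixture
  (1−g)·city_shares + g·one_hot(dominant); dominant grades occupy
  contiguous serpentine blocks sized by the city shares, so the
  segregation knob g moves the Duncan dissimilarity index between
  {AB, C1} and {C2, DE} (measured ≈ 0.21 at g = 0.2 and ≈ 0.57 at
  g = 0.6 on the default suite) and the blocks are larger than a park
  catchment, making segregation spatial rather than merely compositional.
- **Walkability** quartiles are assigned by ranking zones on a blend of
  mean-SES rank and a random rank (weight = walkability–SES correlation,
  default 0.7), reproducing the documented association between walkability
  and neighbourhood status.
- **Parks** (default 12) are placed uniformly; sizes are log-normal
  (median ≈ 5 ha). Catchment = 1600·sqrt(size/mean) m, floored at 800 m;
  "proportional to size" fixes only the monotone relation, and sqrt-area
  scaling (reach ∝ linear dimension) is our choice. A zone is *deprived*
  iff share(C2)+share(DE) > 0.6; small parks (below the city mean) in
  deprived zones are labelled low quality with probability 0.5. Medium and
  high labels are behaviourally identical; only "low" triggers avoidance.
- **Default suite**: four cities spanning the observed contrasts —
  `edleith` (AB+C1 = 0.55, g = 0.2, s = 0.88, the reference), `glasfork`
  (0.35, 0.6, 0.80), `aberdon` (0.53, 0.55, 0.88), `dunlaw` (0.40, 0.4,
  1.0). Sunshine factors follow the published annual-sunshine ordering.
  The two-city mechanism checks use the edleith/glasfork pair.

What the generator does **not** emulate: real street networks (distances
are Euclidean), irregular zone geometries and sizes, within-zone SES
micro-structure, age–SES correlation, and the empirical park size/location
distributions. Passing emergence tests therefore show that the *mechanism*
produces the qualitative pattern under controlled composition/segregation
contrasts — not that the model reproduces any real city's visit counts.

## Parameter sweep, quasi-null, scenario ladder

The sweep covers the Cartesian grid t_mu, ht_mu ∈ {0.3…0.7 step 0.1} ×
h ∈ {0.33, 0.5, 0.66, 1} (100 cells; thresholds are drawn per agent with
σ = 0.05), with 10 replicates per cell by default. Seeds for each
(cell, replicate, city) derive from a SeedSequence over the base seed and
the cell coordinates, so results are independent of execution order and
safe to parallelise; the `--jobs` CLI flag is accepted but execution is
serial — identical output by construction. The quasi-null permutes the
(home, zone) pairs among agents within a city, conserving all attributes
and per-zone head counts while destroying the SES–location link; park
lists are recomputed.

Problem sizes used in the shipped end-to-end checks: the two-city
emergence and quasi-null checks run the 20 000-resident pair at full
1460-day length (10 repeats, and a 3×3×2 coarse grid respectively); the
scenario ladder runs the four-city suite at 10 000 residents per city on
the same coarse grid with one replicate. These sizes were chosen as the
smallest at which the contrasts of interest are comfortably larger than
replicate noise.

## Spatial microsimulation baseline

The MSM module mirrors the structure of the survey-based comparison: a
survey table (age band, gender, ethnicity, SES, visits/year) is raked zone
by zone to four marginal constraint vectors by IPF (order age → gender →
ethnicity → SES per sweep; the order affects the path, not the feasible
fixed point), to tolerance 1e-6 or 200 sweeps. Structural zeros (positive
target, empty survey category) raise an error naming the cell;
non-convergence warns with the achieved deviation. Weights are integerised
by truncate-replicate-sample with the remainder drawn by systematic
sampling on the fractional parts, making expected counts equal weights.
Zone medians of visits/year are compared with ABM per-zone medians by
Pearson correlation (≥ 3 common zones; zero-variance vectors yield NaN
with a warning). The bundled scenario generator builds a feasible
ground-truth population with zone-varying SES tilt and an SES-graded gamma
behaviour model, from which survey and marginals are derived — a synthetic
stand-in for the real survey/census pairing, which is out of scope.

## Numerical choices and degenerate inputs

- Propensity clamp [1e-4, 1]: pure multiplicative decay would otherwise
  make dissatisfied agents numerically unrecoverable.
- Truncation of Normal draws is by clipping; the mass clipped at the
  default parameters is < 0.5% and shifts the mean by < 1e-4.
- Park-list ties (equal distance) break by ascending park id; empty
  accessibility sets fall back to the single nearest park so lists are
  never empty.
- Integer agent counts per zone are round(residents × scale); medians
  include zero-visit agents; a grade absent from a city is reported as
  missing and fails emergence via NaN comparisons.
- All randomness flows through numpy Generators seeded from explicit
  config seeds; a run's config echo reproduces it bit-for-bit.

## Known limitations

- Absolute visit counts are not calibrated to any survey; only ordinal,
  cross-city patterns are meaningful.
- One visit per agent-day, walking access only, no within-day timing.
- The social-influence and quality-avoidance procedures are plausible
  re-specifications of qualitatively described mechanisms and are exposed
  as parameters rather than fixed facts.
- The GeoJSON reader assumes planar metric coordinates; real layouts must
  be projected before use.
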