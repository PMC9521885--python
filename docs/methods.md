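# Methods

## The sensitivity metric

The pipeline scores each building-pooled POI ("unit") by comparing the
crowding it exhibited when residents complained against the crowding it
exhibited when they did not. Activity intensity is visits per 10,000 sq ft
of floor area per six-hour interval; intervals are half-open [t, t + 6h) in
local clock time starting at 00:00/06:00/12:00/18:00, and a unit's interval
is *open* if any pooled member was open during any of its hours. The
absolute threshold A is the arithmetic mean intensity over open intervals
containing at least one complaint; the difference threshold D is the
fractional excess of A over the baseline mean (open, complaint-free
intervals); the sensation value is SS = D · log₁₀ A; and the SDS score is
the inverse min–max rescaling of SS over all scored units in the run,
times 100. Zip scores are unweighted means of member-unit SDS.

Assumptions inherited from this design:

- visit counts are a valid proxy for in-place crowding, and floor-area
  normalization makes them comparable across establishments;
- a complaint is a response to crowding *at that unit in that interval*
  (complaints are attributed to a single building and a single six-hour
  bin; multiple complaints in one bin carry no extra weight);
- the baseline is stationary over the study window — by default all open
  complaint-free intervals pool into one mean. A config switch
  (`stratify_baseline`) instead matches each complaint interval to the
  baseline mean of its own time-of-day slot; it is off by default to keep
  the estimator literal, since the pooled version is the primary one.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| interval length | 6 h | — | balances sparse visit streams against within-day structure; fixed, not configurable |
| intensity unit | per 10,000 sq ft | — | keeps typical A above 1 so log A > 0; SDS is *not* invariant to this unit (D multiplies, log A shifts), so it is pinned and documented |
| `log_base` | 10 | — | decadic log is the convention for Fechner-law presentations; SDS is provably invariant to the base (the min–max normalization absorbs the positive constant), which the suite asserts |
| `min_baseline` | 4 intervals | — | about one day of open baseline before a Weber fraction is trusted; units below it are excluded with a ledger entry |
| `police_low` / `police_high` | 0.3 / 0.6 | rate | strata bounds for the police-response comparison, roughly one standard deviation around a typical citywide mean response rate; overridable |

Negative D (complaint-time density below baseline) and log A < 0 are kept
as computed: flooring would silently compress the lower end of the min–max
range. Units with zero complaints are carried through ingestion but not
scored — the metric is defined only where a response was observed — and
the exclusion is recorded in the filter ledger. Complaint intervals whose
recorded visit count is zero are routed to the ledger rather than diluting
A (a complaint with no measured stimulus is uninterpretable under the
model). All-equal SS across units is a hard error: the normalization is
undefined and silently emitting constants would be worse.

## The synthetic city

The generator emulates the statistical shape of the real inputs with a
known sensitivity structure:

- POIs get a type (six categories with type-specific opening hours), a
  lognormal floor area (median ≈ 4,000 sq ft), and a building id; a stress
  mode packs 2–3 same-zip POIs per building to exercise pooling.
- Hourly visits are Poisson with mean `base_rate` × a 24-hour diurnal
  profile × floor-area scaling, zero when closed. `base_rate` = 3 visits
  per open hour for a 4,000 sq ft unit gives interval intensities of a few
  dozen visits per 10,000 sq ft, sparse enough to resemble storefront
  traffic.
- With probability 0.15 per six-hour interval, a *crowding burst* inflates
  the interval total by a uniform multiplier in [1.5, 3.5]; the inflated
  total is rounded to an integer and the extra visits are apportioned to
  the interval's hours by a seeded multinomial proportional to the existing
  counts, so hourly and interval tables stay mutually consistent.
- A complaint can fire only in an open interval whose intensity exceeds
  (1 + θ_z) times the unit's running mean intensity over prior open,
  non-burst intervals; the first two days are a warm-up with no complaints
  (avoids day-one circularity). Eligible intervals emit a complaint with
  probability `report_prob` = 0.7, time-stamped uniformly within the
  interval. θ_z defaults span 0.05–1.20 across zips; θ = ∞ ("never") is a
  supported sentinel. Complaint randomness uses per-interval uniforms
  shared across θ values, so lowering a zip's threshold can only add
  complaints under a fixed seed (a monotonicity the suite asserts).
- A police-action flag is drawn per complaint from the zip's
  `police_action_prob`, independent of everything else, which makes the
  disparity tests interpretable as pure null or planted-signal designs.
- Covariates are strictly increasing transforms (logistic for shares,
  exponential for income and density, affine for case rates) of
  ±standardized rank(θ_z) plus Gaussian noise (default sd 0.4 on the
  latent scale). With zero noise each covariate is exactly monotone in
  θ_z; ranks rather than raw θ keep the ∞ sentinel usable. Default
  directions encode the documented disparity pattern: income, White share,
  density and vaccination fall with tolerance; Black/minority share,
  Republican share and case rate rise with it.
- One master seed spawns independent child streams per component (POIs,
  visits, bursts, complaints, police flags, covariates), so identical
  configs reproduce byte-identical tables while components stay
  independently perturbable.

What the generator does *not* emulate: spatial correlation between
neighboring zips, device-level mobility (gravity/radiation structure),
weekly seasonality, complaint propensity depending on absolute crowd size
rather than the relative excess, holidays, or weather. Passing tests
therefore certify the estimator's correctness and calibration under the
stated generative law — rank recovery of planted thresholds, sign patterns,
nominal test sizes — not the real-world validity of the visit-density
proxy.

## Numerical and procedural choices

- Intensity is computed as `visits × 10,000 / area` (multiply before
  divide) so integer-visit fixtures produce exact decimals.
- Quartile cut points use linear interpolation between closest ranks;
  ties at a cut go to the lower group; fewer than four zips, or a
  degenerate SDS distribution with coinciding cut points, is a hard error.
- ANOVA uses scipy's one-way F; Tukey HSD comes from statsmodels; the
  police comparison uses Welch (unequal-variance) t-tests. Covariates
  constant across groups and zero-variance correlations are flagged rows,
  not crashes. Missing covariate values are dropped pairwise with the n
  reported — never imputed.
- Complaint-to-unit matching prefers an explicit building id; records with
  only lat/lon are matched point-in-polygon against optional GeoJSON
  features (WGS84 lon/lat, boundary points to the first containing feature
  in file order). Unresolvable complaints go to the ledger.
- Duplicate (unit, hour) rows in the visit stream are a hard error —
  summing them silently would double-count a data defect.
- Every filtering rule appends (rule, rows in, rows out, dropped) to the
  run's ledger, and rows_in − dropped = rows_out is enforced at insert
  time.

## Calibration experiments

The suite's null-calibration check draws covariates independent of the
planted thresholds and police actions independent of demographics, then
verifies both inference layers reject at the nominal 5% level within the
binomial Monte-Carlo band (200 replicates; 120 zips so quartile strata are
populated). The police-response null draws the demographic share from a
normal law: Welch's test assumes approximate normality, and feeding it
heavy-tailed or uniform shares at stratum sizes of two or three inflates
its size — a caveat that applies equally to real-data use of the
Table-style comparison at small zip counts.

Problem sizes: the default study city is 20 zips × 30 units × 60 days
(864,000 hourly rows, ~600 scored units), which recovers planted threshold
ranks with Spearman ≈ 0.99; invariance checks use a 1,000-unit 30-day
city. These sizes were chosen as the smallest at which zip-level rank
recovery stabilizes well clear of the 0.8 design requirement.

## Known limitations

- SDS is a *relative* score: it is defined by the min–max range of the
  units actually scored in a run, so scores are not comparable across runs
  with different unit sets.
- The metric conflates sensitivity with reporting propensity; a
  low-scoring neighborhood may be tolerant or merely unwilling to report.
  The package measures the combination, as any complaint-stream analysis
  must.
- Zip-level inference treats zips as independent units; spatial
  autocorrelation would narrow effective sample sizes.
- The six-hour complaint flag is boolean, so bursty multi-complaint
  intervals carry the same weight as single-complaint ones.
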