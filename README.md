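# sds-sensitivity

Quantify how sensitive a neighborhood is to social-distancing non-compliance
from two observational streams: hourly visit counts at points of interest
(POIs) and resident complaint reports (311-style service requests). The
package is aimed at urban public-health and computational-social-science
researchers who want to separate *how crowded places actually were* from
*how readily residents reported crowding* — a distinction that matters
because complaint-driven enforcement misallocates resources when reporting
propensity varies across neighborhoods.

## The model

Crowding is treated as a psychophysical stimulus and a complaint as the
behavioral response, using the Weber–Fechner threshold framework. For each
scoring unit (POIs pooled to one building), with activity intensity
*I* = visits per 10,000 sq ft per six-hour interval:

- **Absolute threshold** *A* = mean *I* over open intervals in which a
  complaint was reported — the average stimulus that provoked a response.
- **Difference threshold (Weber fraction)**
  *D* = (*A* − *Ī*₀) / *Ī*₀, where *Ī*₀ is the unit's baseline mean
  intensity over open, complaint-free intervals — the just-noticeable
  relative increase in crowding.
- **Subjective sensation** (Fechner's law) *SS* = *D* · log₁₀ *A*.
- **Sensitivity score** *SDS* = |1 − (*SS* − min *SS*)/(max *SS* − min *SS*)| × 100,
  so the most tolerant unit in the run scores 0 and the most sensitive 100.
- **Neighborhood score** *SDS_z* = mean SDS over a zip's scored units.

The analysis layer classifies zips into sensitivity quartiles, compares
neighborhood covariates across quartiles (one-way ANOVA + Tukey HSD),
correlates *SDS_z* with health indicators (Pearson), and tests whether
police responses to complaints differ by neighborhood demographics at fixed
sensitivity (Welch t-tests between low- and high-response zips).

Because the real inputs of such studies are proprietary mobility feeds, the
package ships a synthetic-city generator that plants a known per-zip
reporting threshold θ_z (a complaint can fire only when an interval's
intensity exceeds (1 + θ_z) × the unit's running baseline). Every stage is
validated against this ground truth.

## Worked example

The canonical two-establishment illustration: both units have 10,000 sq ft
and a baseline of 4 visits per six-hour interval; complaints arrive in
intervals with 20 and 6 visits respectively.

```python
>>> from sds import difference_threshold
>>> difference_threshold(20.0, [4, 4, 4, 4])   # crowding had to quadruple
4.0
>>> difference_threshold(6.0, [4, 4, 4, 4])    # a 50% excess sufficed
0.5
```

The 6-visit unit responds to a far smaller relative excess, so after
inverse min–max normalization it gets SDS = 100 (most sensitive) and the
20-visit unit gets 0.

A full synthetic run from the shell:

```bash
sds run --config examples/run.yaml
```

simulates a 6-zip city (planted thresholds from θ = 0.05 to θ = 1.00),
scores 90 units and prints per-neighborhood results to
`results/tutorial/zip_scores.csv`:

```
zip,SDS_z,n_units
z000,78.87,15
z001,71.44,15
z002,69.55,15
z003,53.36,15
z004,52.34,15
z005,32.55,15
```

The recovered ranking exactly mirrors the planted tolerances: z000, which
reports at a 5% excess over baseline, is the most sensitive neighborhood;
z005, which tolerates a doubling, is the least. `sds report --results
results/tutorial` renders the tables (quartiles, ANOVA, correlations,
police-response comparison) plus the citywide complaint-vs-baseline
intensity curves as one markdown document.

Stages can also be run separately — `sds simulate`, `sds ingest`,
`sds score`, `sds neighborhoods` — passing CSVs of your own data; see
`docs/data_dictionary.md` for every column contract.

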