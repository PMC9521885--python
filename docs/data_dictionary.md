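# Data dictionary

All files are UTF-8 comma-separated CSV with ISO-8601 local timestamps
(no timezone arithmetic anywhere in the pipeline).

## Inputs

### poi.csv
| column | type | meaning |
|---|---|---|
| poi_id | str | unique establishment identifier |
| building_id | str | building (tax-lot) identifier used for pooling |
| zip | str | neighborhood identifier |
| poi_type | str | establishment category (e.g. food_drink, grocery) |
| floor_area | float > 0 | floor area in square feet |

### visits.csv (long format, one row per POI per hour)
| column | type | meaning |
|---|---|---|
| poi_id | str | establishment |
| timestamp | datetime | start of the hour |
| visits | int >= 0 | visit count in that hour |
| open | 0/1 | whether the establishment was open |

### complaints.csv
| column | type | meaning |
|---|---|---|
| complaint_id | str | unique report identifier |
| timestamp | datetime | when the report was filed |
| building_id | str | building of the offending unit (lat/lon + GeoJSON polygon fallback supported) |
| descriptor | str | complaint category text |
| resolution | str | free-text outcome |
| police_action | 0/1 | whether the resolution indicates a police response |

### covariates.csv
One row per zip; `zip` plus any of: `median_income` ($), `nh_white_share`,
`black_share`, `minority_share`, `republican_share`, `vaccination_rate`
(fractions in [0, 1]), `population_density` (residents per sq mile),
`case_rate` (confirmed cases per 10,000 residents).

## Outputs

### thresholds.csv (one row per scored unit)
| column | meaning |
|---|---|
| unit_id | building-pooled scoring unit |
| A | absolute threshold: mean intensity (visits per 10,000 sq ft per 6 h) over complaint intervals |
| D | difference threshold (Weber fraction): (A - baseline mean) / baseline mean |
| SS | subjective sensation D x log10(A) |
| SDS | sensitivity score in [0, 100], inverse min-max of SS |
| n_complaint_intervals | open complaint intervals with recorded visits |
| n_baseline_intervals | open complaint-free intervals |
| zip, poi_type | unit metadata |

### zip_scores.csv
`zip`, `SDS_z` (mean SDS of the zip's scored units), `n_units`.

### curves.csv
`interval_start`, `complaint_intensity`, `baseline_intensity`: citywide mean
intensity per six-hour slot over complaint-flagged vs unflagged open
intervals; empty strata are blank (missing), not zero.

### type_summary.csv
Per establishment type: `n_units`, `complaint_volume` (complaint intervals),
`unit_share_pct`, `mode_hour` (modal complaint clock hour, ties to the
earliest), mean and sd of A, D and SDS; sorted by mean SDS descending.

### quartiles.csv
`zip`, `quartile` in {low, medium-low, medium-high, high}; cut points at the
25th/50th/75th percentiles of SDS_z, ties to the lower group.

### group_comparison.csv
Long table: per covariate one `kind = anova` row (group means/sds, F, p, n,
flag) and six `kind = tukey` rows (pair, mean difference, adjusted p, reject).

### correlations.csv
`indicator`, Pearson `r`, `p`, `n`, `flag` (zero-variance inputs flagged).

### police_comparison.csv
Per sensitivity quartile: counts and mean demographic share of zips with
police-action rate below `police_low` vs above `police_high`, Welch t and p;
quartiles with a stratum smaller than two zips are flagged.

### ledger.json / manifest.json
Ordered filter ledger (rule, rows in/out/dropped) and the run manifest
(config hash, file hashes, package version, stage timestamps).
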