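# A small synthetic city for the tutorial run: 6 neighborhoods spanning
# tolerant (theta = 1.0: crowding must double the baseline before anyone
# reports) to sensitive (theta = 0.05), four weeks of hourly visits.
n_zips: 6
pois_per_zip: 15
study_start: 2020-03-28
study_end: 2020-04-25
base_rate: 3.0
crowding_burst_prob: 0.15
burst_multiplier_range: [1.5, 3.5]
report_prob: 0.7
planted_threshold:
  z000: 0.05
  z001: 0.20
  z002: 0.40
  z003: 0.60
  z004: 0.80
  z005: 1.00
police_action_prob:
  z000: 0.45
  z001: 0.45
  z002: 0.45
  z003: 0.45
  z004: 0.45
  z005: 0.45
seed: 42
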