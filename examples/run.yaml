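# Tutorial end-to-end run: simulate the small city, score it, and analyze
# neighborhood disparities. Outputs land in results/tutorial.
synthetic:
  n_zips: 6
  pois_per_zip: 15
  study_start: 2020-03-28
  study_end: 2020-04-25
  planted_threshold:
    z000: 0.05
    z001: 0.20
    z002: 0.40
    z003: 0.60
    z004: 0.80
    z005: 1.00
  seed: 42
out_dir: results/tutorial
seed: 42
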