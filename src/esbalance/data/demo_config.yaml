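# Bundled synthetic demo: a small five-date scene with twelve zones.
mode: synthetic
seed: 42
outdir: demo_out
landscape:
  grid_shape: [48, 48]
  cell_area: 1.0
  years: [2000, 2005, 2010, 2015, 2020]
  n_zones: 12
  seed: 42
balance_mode: normalized
k_levels: 5
k_balance: 7
per_year_breaks: true
regression:
  run: true
  thetas: [0.1, 0.3, 0.5, 0.7, 0.9]
  n_boot: 200
  pool_years: true
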