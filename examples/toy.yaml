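seed: 0
domain:
  bounds:
  - -6.0
  - -5.0
  - 56.0
  - 57.2
  cell_size: 0.02
  coast_lon: -5.5
  fjords:
  - - -5.5
    - -5.3
    - 56.2
    - 56.3
  - - -5.5
    - -5.3
    - 56.9
    - 57.0
flow:
  mean_current_speed: 0.0
  tidal_amplitude: 0.15
  noise_speed: 0.02
  diffusivity_D: 5.0
  seed: 1
sites:
- id: Bay1_west
  lon: -5.46
  lat: 56.25
  kind: farm
- id: Bay1_east
  lon: -5.41
  lat: 56.25
  kind: farm
- id: Bay2_west
  lon: -5.46
  lat: 56.95
  kind: farm
- id: Bay2_east
  lon: -5.41
  lat: 56.95
  kind: farm
sim:
  release_rate: 2
  release_days: 1.0
  total_days: 4.0
  settle_window_days: 2.0
  settle_radius_m: 2000.0
  dt_s: 360.0
  seed: 2
starts:
- '2021-02-01'
genetics:
  n_per_pop: 30
  n_loci: 300
  target_fst: 0.2
  missing_rate: 0.05
  n_boot: 200
  K: null
  seed: 3
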