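# A boot-shaped peninsula on a coarse 1-degree grid: elongated north-west to
# south-east with a toe kicking west and two islands omitted. Urban poles
# emulate the familiar north-heavy population with a concentrated trial
# landscape.
name: Bootland
lat_min: 37.0
lat_max: 46.0
lon_min: 7.0
lon_max: 18.0
spacing_deg: 1.0
population_pattern: urban_poles
n_poles: 4
pole_mass_share: 0.6
total_population: 60000000
incidence_rate: 691.2
site_policy: concentrated
n_locations: 4
trials_per_year_mean: 20.0
years: [2019]
seed: 42
mask:
  - "011111100000"
  - "111111110000"
  - "011111100000"
  - "000111111000"
  - "000011111100"
  - "000001111110"
  - "000000111111"
  - "000000011110"
  - "000000111100"
  - "000001111000"
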