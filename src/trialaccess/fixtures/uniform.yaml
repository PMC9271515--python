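# Evenly spread population, proportional (hence equal) site allocation.
name: Uniformia
lat_min: 50.0
lat_max: 53.0
lon_min: 20.0
lon_max: 24.0
spacing_deg: 0.5
population_pattern: uniform
total_population: 4000000
incidence_rate: 280.0
site_policy: proportional
n_locations: 3
trials_per_year_mean: 8.0
years: [2019]
seed: 13
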