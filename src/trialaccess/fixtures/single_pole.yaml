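# One metropolis holding 90% of the population, uniform countryside.
name: SinglePole
lat_min: 45.0
lat_max: 48.0
lon_min: 4.0
lon_max: 8.0
spacing_deg: 0.5
population_pattern: urban_poles
n_poles: 1
pole_mass_share: 0.9
total_population: 6000000
incidence_rate: 350.0
site_policy: concentrated
n_locations: 2
trials_per_year_mean: 10.0
years: [2018, 2019]
seed: 11
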