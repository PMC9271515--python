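# Symmetric two-lobe toy: two equal population masses at randomly drawn
# cells, nothing in between. With a site at one lobe, the optimizer's first
# placement must land on the other.
name: TwoLobe
lat_min: 40.0
lat_max: 42.0
lon_min: 10.0
lon_max: 14.0
spacing_deg: 1.0
population_pattern: urban_poles
n_poles: 2
pole_mass_share: 1.0
pole_equal_masses: true
total_population: 2000000
incidence_rate: 400.0
site_policy: concentrated
n_locations: 1
trials_per_year_mean: 6.0
years: [2019]
seed: 7
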