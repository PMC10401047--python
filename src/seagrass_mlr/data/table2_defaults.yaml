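# Default parameterization for Cymodocea nodosa carbon-balance models.
# Rates are hourly; irradiance in µmol quanta m^-2 s^-1; biomass in g DW m^-2.

light_reference:
  full_sun_instantaneous: 858.04   # µmol quanta m^-2 s^-1 == 100% SI
  daylight_fraction: 0.5           # photosynthesis active 12 h of 24 h

non_acclimation:
  pmax: 11.64        # mg O2 g^-1 ABG DW h^-1 (high-light acclimated)
  ik: 70.04809       # µmol quanta m^-2 s^-1
  r: 1.987           # mg O2 g^-1 ABG DW h^-1

acclimation:
  pmax: {high: 11.64,    low: 2.096,    slope: 0.008524, inflection: -49.1}
  ik:   {high: 70.04809, low: 24.54396, slope: 0.00863,  inflection: 177.45783}
  r:    {high: 1.987,    low: 1.509,    slope: 0.4567,   inflection: 267.1}

below_ground:
  bar: 1.0           # below- to above-ground biomass ratio, dimensionless
  rrr: 0.1987        # root/rhizome respiration = R_max / 10

biomass_growth_mortality:
  conversion_k: 0.001075   # g total DW per mg O2 evolved
  carrying_capacity: 100.0 # g DW m^-2
  d0: 0.000116             # baseline mortality, h^-1
  lambda_b: 0.05           # facilitation slope, (g DW m^-2)^-1
  b0: 10.0                 # facilitation threshold biomass, g DW m^-2
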