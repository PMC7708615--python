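# Default Baltic Sea station, basin and load configuration.
#
# Stations: Swedish national monitoring stations; the tube interval sets the
# depth correction (2 for 0-20 m tubes, 1 for 0-10 m tubes).
# Areas: basin surface areas in km^2.
# External inputs and allowable limits: HELCOM figures in kt N per year,
# consumed as configuration (not recomputed here); where two periods are
# listed both are retained.
stations:
  B1: {basin: baltic_proper, tube: [0, 20]}
  BY31: {basin: baltic_proper, tube: [0, 20]}
  BY15: {basin: baltic_proper, tube: [0, 10]}
  BY5: {basin: baltic_proper, tube: [0, 10]}
  BY2: {basin: baltic_proper, tube: [0, 10]}
  C3: {basin: bothnian_sea, tube: [0, 10]}
  B3+B7: {basin: bothnian_sea, tube: [0, 10]}
  F9/A13: {basin: bothnian_bay, tube: [0, 10]}

basins:
  baltic_proper:
    area_km2: 211000
    pooling_years: 1
    allowable_limit_kt: 325
  bothnian_sea:
    area_km2: 79000
    pooling_years: 6
    allowable_limit_kt: 79
  bothnian_bay:
    area_km2: 36800
    pooling_years: 6
    allowable_limit_kt: null

external_inputs:
  baltic_proper:
    - {period: [1999, 2017], total_kt_per_year: 374}
    - {period: [2013, 2017], total_kt_per_year: 345}
  bothnian_sea:
    - {period: [2012, 2017], total_kt_per_year: 69}

# Areas used only for areal-rate extrapolation to unmonitored basins.
extrapolation_areas_km2:
  gulf_of_finland: 29600
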