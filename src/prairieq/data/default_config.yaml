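# Default pipeline parameterization. Constants here follow the published
# prairie grassland-bird analysis: half-saturation 0.20, suitable-habitat
# threshold 0.3, well buffers 100 m, turbine buffers 30 m, nested
# conservation-grassland conversion fractions 10/25/50/75/100 %.
quality:
  half_saturation: 0.20
  exponent: 2.5
  accessibility: 1.0
  suitability_threshold: 0.3
buffers:
  well_m: 100.0
  turbine_m: 30.0
scenario_fractions: [0.10, 0.25, 0.50, 0.75, 1.00]
tables:
  habitat_sensitivity: habitat_sensitivity.csv
  threats: threats.csv
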