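# Published region-wide (total-row) areas (ha) of suitable grassland-bird
# habitat lost and degraded under three threat scenarios in the U.S. Prairie
# Pothole Region, 2014 land cover, with the degradation percentage as printed
# (relative to the 2014 baseline suitable area).
scenario,baseline_ha,lost_ha,degraded_ha,printed_pct_degraded
cropland,11536402,5981,2148384,-19
energy,11536402,59877,1890723,-16
crp_value,11536402,951,1503366,-13
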