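# Habitat suitability (HABITAT) and per-threat sensitivity by land-cover class.
# HABITAT weights follow the published parameterization for prairie grassland
# birds (grassland/conservation grassland 1.0, small grains 0.5, fallow 0.3,
# non-habitat 0). Sensitivity values are representative stand-ins ordered so
# that woodland and urban exert the greatest influence on habitat classes.
class,habitat,woodland,urban,cropland,roads,energy
native prairie,1.0,1.0,1.0,0.7,0.5,0.6
CRP grassland,1.0,1.0,1.0,0.7,0.5,0.6
hayland,1.0,0.9,0.9,0.6,0.4,0.5
small grains,0.5,0.6,0.6,0.4,0.3,0.4
fallow,0.3,0.5,0.5,0.3,0.2,0.3
row crop,0.0,0.0,0.0,0.0,0.0,0.0
woodland,0.0,0.0,0.0,0.0,0.0,0.0
urban,0.0,0.0,0.0,0.0,0.0,0.0
water,0.0,0.0,0.0,0.0,0.0,0.0
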