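# Threat weights and maximum influence distances. Weights are ordered per the
# published parameterization (woodland and urban greatest); the cropland
# influence distance of 100 m matches the published analysis. The remaining
# distances and weights are representative stand-ins.
threat,weight,max_distance_m,decay
woodland,1.0,250,linear
urban,1.0,500,linear
cropland,0.5,100,linear
roads,0.4,250,linear
energy,0.7,500,linear
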