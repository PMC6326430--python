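# Published suitable grassland-bird habitat areas (ha) for the U.S. Prairie
# Pothole Region ecoregions, 2014 baseline and nested conservation-grassland
# conversion scenarios, with the loss percentages as printed (printed_decimals
# gives the precision of the printed percentage). Two area cells carried
# evident typesetting errors in print and are stored here in the form
# consistent with their own printed percentages (NGP at fractions 0.25, 0.75).
region,crp_fraction_converted,baseline_ha,scenario_ha,printed_pct,printed_decimals
NGP,0.10,5256073,5201350,-1,0
NGP,0.25,5256073,5117941,-2.6,1
NGP,0.50,5256073,4982635,-5.2,1
NGP,0.75,5256073,4849494,-7.7,1
NGP,1.00,5256073,4713048,-10.3,1
NWGP,0.10,4751631,4736025,-0.3,1
NWGP,0.25,4751631,4713506,-0.8,1
NWGP,0.50,4751631,4675765,-1.6,1
NWGP,0.75,4751631,4635920,-2.4,1
NWGP,1.00,4751631,4597735,-3.2,1
LAP,0.10,1070319,1049800,-1.9,1
LAP,0.25,1070319,1019354,-4.8,1
LAP,0.50,1070319,968130,-9.6,1
LAP,0.75,1070319,915492,-14.5,1
LAP,1.00,1070319,865272,-19.2,1
DML,0.10,457427,440827,-3.6,1
DML,0.25,457427,415275,-9.2,1
DML,0.50,457427,373533,-18.3,1
DML,0.75,457427,332627,-27.3,1
DML,1.00,457427,291988,-36.2,1
Total,0.10,11535451,11428001,-0.9,1
Total,0.25,11535451,11266075,-2.3,1
Total,0.50,11535451,11000062,-4.6,1
Total,0.75,11535451,10733532,-7.0,1
Total,1.00,11535451,10468042,-9,0
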