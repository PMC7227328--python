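lulc,error_050_pct,error_047_pct
Riparian forest and woodland,5.52,-0.81
Savannah Woodland,6.54,0.15
Shrub Savannah,6.41,0.54
Savannah grassland,8.21,1.72
Cropland and Fallow,7.6,1.14
Settlements,5.53,-0.80
Agroforestry,7.65,1.19
Plantation,4.72,-1.55
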