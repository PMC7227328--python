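category,total_stock,se_total
Forest land,159841.01,8721.48
Grassland,161.55,15.23
Cropland,12272.24,2326.92
Settlements,1125.66,1187.20
Agroforestry,442.91,138.47
Plantation,1504.36,435.29
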