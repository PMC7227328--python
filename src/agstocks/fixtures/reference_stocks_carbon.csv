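lulc,category,min_density,max_density,mean_density,se_density,total_stock,se_total
Riparian forest and woodland,Forest land,35.46,57.27,44.81,2.38,15291.86,813.16
Savannah Woodland,Forest land,12.50,31.90,21.25,1.16,116401.70,6397.49
Shrub Savannah,Forest land,2.76,12.22,6.57,0.35,28147.43,1510.82
Savannah grassland,Grassland,0.03,2.98,1.67,0.15,161.55,15.23
Cropland and Fallow,Cropland,0.03,4.33,1.52,0.14,12272.24,2326.92
Settlements,Settlements,0.41,4.57,2.30,0.48,1125.66,1187.20
Cashew plantation,Agroforestry,4.99,98.08,21.39,6.68,442.91,138.47
Eucalyptus grandis,Plantation,3.67,331.91,97.83,27.55,1346.27,379.15
Tectona grandis,Plantation,16.52,108.70,82.62,33.09,74.36,29.78
Azadirachta indica,Plantation,31.58,117.87,88.02,28.23,63.37,0.32
Gmelina arborea,Plantation,4.88,16.16,11.82,3.50,20.34,6.02
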