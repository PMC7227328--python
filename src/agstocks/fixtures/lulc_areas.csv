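lulc,category,area_ha,percent_of_basin,plot_width_m,plot_length_m,n_plots
Riparian forest and woodland,Forest land,320.40,1.66,30,30,9
Savannah Woodland,Forest land,5447.79,28.29,30,30,27
Shrub Savannah,Forest land,4241.88,22.03,30,30,56
Savannah grassland,Grassland,96.48,0.50,30,30,34
Cropland and Fallow,Cropland,8031.15,41.70,30,30,80
Settlements,Settlements,486.72,2.53,100,100,8
Agroforestry,Agroforestry,20.70,0.11,10,20,13
Plantation,Plantation,16.74,0.09,10,20,23
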