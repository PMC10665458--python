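climate_zone,f_lu_grassland,f_mg_grassland,f_i_grassland,f_lu_cropland,f_mg_cropland,f_i_cropland
cool_temperate_moist,1.0,1.14,1.0,0.69,1.0,0.95
cool_temperate_dry,1.0,1.14,1.0,0.80,1.0,0.95
warm_temperate_moist,1.0,1.14,1.0,0.69,1.0,0.95
warm_temperate_dry,1.0,1.14,1.0,0.80,1.0,0.95
tropical_moist,1.0,1.14,1.0,0.58,1.0,0.92
tropical_dry,1.0,1.14,1.0,0.92,1.0,0.92
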