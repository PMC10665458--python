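climate_zone,soil_type,soc_ref_t_ha
cool_temperate_moist,high_activity_clay,95
cool_temperate_moist,low_activity_clay,85
cool_temperate_moist,sandy,71
cool_temperate_dry,high_activity_clay,50
cool_temperate_dry,low_activity_clay,33
cool_temperate_dry,sandy,34
warm_temperate_moist,high_activity_clay,88
warm_temperate_moist,low_activity_clay,63
warm_temperate_moist,sandy,34
warm_temperate_dry,high_activity_clay,38
warm_temperate_dry,low_activity_clay,24
warm_temperate_dry,sandy,19
tropical_moist,high_activity_clay,65
tropical_moist,low_activity_clay,47
tropical_moist,sandy,39
tropical_dry,high_activity_clay,38
tropical_dry,low_activity_clay,35
tropical_dry,sandy,19
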