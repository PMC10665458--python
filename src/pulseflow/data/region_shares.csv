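region,ch4_share,n2o_share,area_mha,soc_t_ha
North America,0.100,0.12,230,40
Latin America & Caribbean,0.220,0.18,420,38
South Asia,0.270,0.17,60.4,28
East & Southeast Asia,0.100,0.12,330,45
West & Central Asia,0.050,0.05,220,30
North Africa,0.020,0.02,50,20
Sub-Saharan Africa,0.140,0.20,400,25
West Europe,0.035,0.05,60,60
East Europe,0.015,0.02,120,70
South Europe,0.020,0.02,45,45
Oceania,0.030,0.05,160,35
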