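region_class,cattle_class,ef_kg_head_yr
North America,dairy,138
North America,other,64
Western Europe,dairy,126
Western Europe,other,52
Eastern Europe,dairy,103
Eastern Europe,other,58
Oceania,dairy,90
Oceania,other,60
Latin America,dairy,78
Latin America,other,56
East & Southeast Asia,dairy,68
East & Southeast Asia,other,47
Middle East,dairy,76
Middle East,other,49
Africa,dairy,46
Africa,other,41
Indian Subcontinent,dairy,58
Indian Subcontinent,other,41
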