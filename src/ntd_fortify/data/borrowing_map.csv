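quantity,target_country,source_countries
prevalence,LU,CH
prevalence,GR,IT
prevalence,CY,IT
prevalence,EE,FI
prevalence,RO,PL
prevalence,LV,PL;FI;SE
prevalence,LT,PL;FI;SE
folate,LU,CH
folate,BG,PL
folate,CY,GR
folate,LV,PL
folate,LT,PL
folate,MT,GR
folate,RO,PL
folate,SI,PL
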