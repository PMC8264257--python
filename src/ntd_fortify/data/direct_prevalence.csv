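country_code,country_name,prevalence_per_1000,source
SK,Slovak Republic,0.53,B20
SI,Slovenia,0.74,B21
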