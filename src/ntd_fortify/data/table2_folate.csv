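country_code,country_name,eu_2017,eu_1998,statistic_kind,median_nmol_l,log_sd,source_country,estimated_from_prevalence,source
AT,Austria,Y,Y,median,11.5,0.77,,false,B23
BE,Belgium,Y,Y,median,13.8,0.41,,false,B24
DK,Denmark,Y,Y,median,8.6,0.29,,false,B25
FI,Finland,Y,Y,median,12.4,0.55,,false,B26
FR,France,Y,Y,median,14.8,0.58,,false,B27
DE,Germany,Y,Y,median,14.3,0.41,,false,B28
GR,Greece,Y,Y,median,17.4,0.69,,false,B29
IE,Ireland,Y,Y,median,16.2,0.53,,false,B30
IT,Italy,Y,Y,median,10.4,0.45,,false,B31
LU,Luxembourg,Y,Y,median,,,CH,false,values from Switzerland used
NL,Netherlands,Y,Y,median,7.3,0.48,,false,B32;B33
PT,Portugal,Y,Y,median,15.2,0.42,,false,B34
ES,Spain,Y,Y,median,16.5,0.51,,false,B35
SE,Sweden,Y,Y,median,15.0,0.40,,false,B36
GB,United Kingdom,Y,Y,median,16.2,0.54,,false,B30
BG,Bulgaria,Y,N,median,,,PL,false,values from Poland used
HR,Croatia,Y,N,median,9.1,,,false,B37
CY,Cyprus,Y,N,median,,,GR,false,values from Greece used
CZ,Czech Republic,Y,N,median,14.0,0.38,,false,B38
EE,Estonia,Y,N,median,12.4,0.60,,false,B39
HU,Hungary,Y,N,median,19.0,0.45,,false,B38
LV,Latvia,Y,N,median,,,PL,false,values from Poland used
LT,Lithuania,Y,N,median,,,PL,false,values from Poland used
MT,Malta,Y,N,median,,,GR,false,values from Greece used
PL,Poland,Y,N,median,14.3,0.52,,false,B40
RO,Romania,Y,N,median,,,PL,false,values from Poland used
SK,Slovak Republic,Y,N,median,16.0,0.35,,false,B41
SI,Slovenia,Y,N,median,,,PL,false,values from Poland used
NO,Norway,N,N,median,7.3,0.50,,false,B42
CH,Switzerland,N,N,median,14.3,0.67,,false,B43
UA,Ukraine,N,N,median,3.2,,,true,estimated from prevalence of NTDs
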