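country_code,country_name,eu_2017,eu_1998,aggregate,prevalence_per_1000,fortified_prevalence_nosupp,pct_reduction_nosupp,prevented_nosupp,fortified_prevalence_supp,pct_reduction_supp,prevented_supp
AT,Austria,Y,Y,false,0.71,0.53,25,279,0.57,19,209
BE,Belgium,Y,Y,false,0.75,0.60,20,369,0.63,15,276
DK,Denmark,Y,Y,false,1.12,0.80,28,394,0.88,21,296
FI,Finland,Y,Y,false,0.90,0.70,23,234,0.75,17,175
FR,France,Y,Y,false,1.16,0.93,20,3735,0.99,15,2801
DE,Germany,Y,Y,false,1.02,0.82,20,2893,0.87,15,2170
GR,Greece,Y,Y,false,0.57,0.46,18,214,0.49,14,160
IE,Ireland,Y,Y,false,0.93,0.75,18,222,0.80,14,166
IT,Italy,Y,Y,false,0.57,0.43,25,1526,0.46,19,1145
LU,Luxembourg,Y,Y,false,0.87,0.70,20,20,0.74,15,15
NL,Netherlands,Y,Y,false,0.82,0.55,32,962,0.62,24,721
PT,Portugal,Y,Y,false,0.43,0.35,19,168,0.37,14,126
ES,Spain,Y,Y,false,0.85,0.69,18,1332,0.73,14,999
SE,Sweden,Y,Y,false,0.79,0.64,19,315,0.67,14,237
GB,United Kingdom,Y,Y,false,1.22,0.99,18,3344,1.05,14,2508
BG,Bulgaria,Y,N,false,1.63,1.26,22,510,1.35,17,382
HR,Croatia,Y,N,false,0.49,0.36,28,112,0.39,21,84
CY,Cyprus,Y,N,false,0.57,0.47,17,25,0.49,13,18
CZ,Czech Republic,Y,N,false,0.73,0.59,20,306,0.62,15,230
EE,Estonia,Y,N,false,0.90,0.70,23,58,0.75,17,43
HU,Hungary,Y,N,false,0.64,0.54,16,193,0.56,12,145
LV,Latvia,Y,N,false,0.82,0.64,22,77,0.68,17,58
LT,Lithuania,Y,N,false,0.82,0.64,22,115,0.69,17,86
MT,Malta,Y,N,false,0.92,0.76,17,13,0.80,13,10
PL,Poland,Y,N,false,0.77,0.61,20,1173,0.65,15,879
RO,Romania,Y,N,false,0.77,0.61,22,746,0.65,17,559
SK,Slovak Republic,Y,N,false,0.53,0.43,18,106,0.46,13,80
SI,Slovenia,Y,N,false,0.74,0.57,22,65,0.62,17,49
NO,Norway,N,N,false,0.84,0.57,32,312,0.63,24,234
CH,Switzerland,N,N,false,0.87,0.69,21,286,0.73,16,214
UA,Ukraine,N,N,false,1.80,0.91,49,8047,1.13,37,6035
EU15,Countries in EU in 1998,,,true,0.95,,21,16007,,15,12005
EU28,Countries in EU in 2019,,,true,0.92,,21,19504,,15,14628
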