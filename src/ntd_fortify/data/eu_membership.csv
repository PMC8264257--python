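country_code,country_name,eu_1998,eu_2017
AT,Austria,Y,Y
BE,Belgium,Y,Y
DK,Denmark,Y,Y
FI,Finland,Y,Y
FR,France,Y,Y
DE,Germany,Y,Y
GR,Greece,Y,Y
IE,Ireland,Y,Y
IT,Italy,Y,Y
LU,Luxembourg,Y,Y
NL,Netherlands,Y,Y
PT,Portugal,Y,Y
ES,Spain,Y,Y
SE,Sweden,Y,Y
GB,United Kingdom,Y,Y
BG,Bulgaria,N,Y
HR,Croatia,N,Y
CY,Cyprus,N,Y
CZ,Czech Republic,N,Y
EE,Estonia,N,Y
HU,Hungary,N,Y
LV,Latvia,N,Y
LT,Lithuania,N,Y
MT,Malta,N,Y
PL,Poland,N,Y
RO,Romania,N,Y
SK,Slovak Republic,N,Y
SI,Slovenia,N,Y
NO,Norway,N,N
CH,Switzerland,N,N
UA,Ukraine,N,N
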