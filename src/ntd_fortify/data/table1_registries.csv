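country_code,country_name,eu_2017,eu_1998,registry_name,first_year,last_year,cases_total,prevalence_per_1000,coverage_pct,associate
BE,Belgium,Y,Y,Antwerp,1998,2016,271,0.73,15,false
BE,Belgium,Y,Y,Hainaut,1998,2017,194,0.79,10,false
DK,Denmark,Y,Y,Odense,1998,2015,105,1.14,7,false
FR,France,Y,Y,Auvergne,2002,2015,170,1.05,1,false
FR,France,Y,Y,Brittany,2011,2017,321,1.31,2,false
FR,France,Y,Y,Paris,1998,2017,634,1.13,3,false
IT,Italy,Y,Y,Emilia Romagna,1998,2017,391,0.57,6,false
IT,Italy,Y,Y,Tuscany,1998,2017,317,0.56,5,false
IE,Ireland,Y,Y,Cork and Kerry,1998,2017,210,1.16,14,false
IE,Ireland,Y,Y,Dublin,1998,2012,255,0.70,28,false
IE,Ireland,Y,Y,SE Ireland,1998,2016,137,1.05,10,false
NL,Netherlands,Y,Y,North Netherlands,1998,2017,291,0.81,10,false
GB,United Kingdom,Y,Y,East Midlands and South Yorkshire,1998,2017,1288,1.13,8,false
GB,United Kingdom,Y,Y,Northern England,2000,2017,775,1.35,4,false
GB,United Kingdom,Y,Y,South West England,2005,2017,717,1.12,4,false
GB,United Kingdom,Y,Y,Thames Valley,1998,2017,448,1.04,3,false
GB,United Kingdom,Y,Y,Wales,1998,2017,942,1.41,4,false
GB,United Kingdom,Y,Y,Wessex,1998,2017,684,1.20,4,false
PT,Portugal,Y,Y,S. Portugal,1998,2017,156,0.43,18,false
ES,Spain,Y,Y,Basque,1998,2016,374,1.02,4,false
ES,Spain,Y,Y,Valencian Region,2007,2016,293,0.60,6,false
DE,Germany,Y,Y,Mainz,1998,2014,89,1.63,0,false
DE,Germany,Y,Y,Saxony-Anhalt,1998,2017,308,0.92,2,false
AT,Austria,Y,Y,Styria,1998,2014,129,0.73,11,false
FI,Finland,Y,Y,Finland,1998,2014,899,0.91,86,true
SE,Sweden,Y,Y,Sweden,2007,2016,803,0.73,53,true
HR,Croatia,Y,N,Zagreb,1998,2017,60,0.49,15,false
MT,Malta,Y,N,Malta,1998,2016,73,0.92,96,false
PL,Poland,Y,N,Wielkopolska,1999,2017,517,0.73,9,false
BG,Bulgaria,Y,N,Sofia,1998,1999,40,2.07,1,true
HU,Hungary,Y,N,Hungary,1998,2012,953,0.66,76,true
CZ,Czech Republic,Y,N,Czech Republic,2000,2010,848,0.74,55,true
CH,Switzerland,N,N,Vaud,1998,2017,135,0.87,10,false
NO,Norway,N,N,Norway,1999,2016,907,0.84,92,false
UA,Ukraine,N,N,Ukraine,2005,2016,650,1.80,4,false
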