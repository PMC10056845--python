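country_code,year,p5,p95
COD,2000,28.5,75.3
COD,2019,1.5,17.5
ETH,2000,39.6,87.5
ETH,2019,1.6,32.4
IND,2000,7.2,59.7
IND,2019,1.6,21.3
BGD,2000,3.3,17.7
BGD,2019,,
BDI,2000,10.2,27.3
BDI,2019,1.5,3.9
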