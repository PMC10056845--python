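country_code,name,national_2000,national_2019,national_change_pp,national_change_pct,gap_2000,gap_2019,gap_change_pp,gap_change_pct,exemplar_absolute,exemplar_relative
AFG,Afghanistan,53.4,14.5,-39.0,-72.9,39.0,31.8,-7.2,-18.5,0,0
AGO,Angola,46.3,24.8,-21.5,-46.4,38.6,37.2,-1.3,-3.5,0,0
BGD,Bangladesh,8.8,0.2,-8.6,-98.0,14.4,0.0,-14.4,-99.9,0,1
BEN,Benin,11.3,13.6,2.4,21.1,16.9,19.9,3.0,18.0,0,0
BFA,Burkina Faso,23.8,4.6,-19.2,-80.6,31.2,10.7,-20.5,-65.8,0,0
BDI,Burundi,18.4,2.3,-16.0,-87.3,17.1,2.4,-14.7,-85.9,0,1
KHM,Cambodia,22.8,7.3,-15.6,-68.2,27.2,18.6,-8.6,-31.6,0,0
CMR,Cameroon,26.4,17.4,-9.0,-34.1,48.7,25.8,-22.9,-47.0,0,0
CAF,Central African Rep,44.0,28.9,-15.1,-34.3,19.1,19.7,0.6,3.1,0,0
TCD,Chad,59.7,24.0,-35.6,-59.7,40.4,36.4,-4.0,-10.0,0,0
COM,Comoros,19.1,6.8,-12.3,-64.6,7.5,3.2,-4.3,-57.5,0,0
COG,Congo,48.5,33.2,-15.3,-31.5,22.2,30.6,8.4,38.1,0,0
CIV,Cote d'Ivoire,17.9,2.3,-15.6,-87.1,20.5,4.4,-16.1,-78.4,0,0
COD,Dem Rep of the Congo,51.9,6.9,-45.0,-86.8,46.8,16.0,-30.8,-65.8,1,0
DJI,Djibouti,34.3,26.1,-8.2,-24.0,17.2,18.0,0.7,4.4,0,0
ERI,Eritrea,10.6,1.1,-9.4,-89.2,15.3,3.8,-11.4,-74.8,0,0
ETH,Ethiopia,63.4,11.7,-51.6,-81.5,47.9,30.8,-17.2,-35.8,1,0
GMB,Gambia,8.6,3.8,-4.8,-55.7,9.4,4.2,-5.2,-55.7,0,0
GHA,Ghana,12.5,6.5,-6.0,-48.2,26.2,5.6,-20.6,-78.7,0,0
GIN,Guinea,35.6,38.4,2.8,7.9,33.2,39.3,6.1,18.4,0,0
GNB,Guinea-Bissau,19.5,6.6,-12.9,-66.3,13.4,7.8,-5.6,-41.7,0,0
HTI,Haiti,20.5,21.0,0.6,2.8,17.9,9.7,-8.2,-45.7,0,0
IND,India,30.9,7.2,-23.6,-76.5,52.5,19.7,-32.7,-62.4,1,0
KEN,Kenya,9.6,10.0,0.4,4.4,16.6,20.8,4.1,24.8,0,0
KGZ,Kyrgyzstan,10.3,5.0,-5.3,-51.5,7.0,5.0,-2.1,-29.3,0,0
LAO,Laos,30.8,24.6,-6.1,-19.9,28.4,21.5,-6.9,-24.4,0,0
LSO,Lesotho,13.1,9.6,-3.5,-26.9,4.3,3.3,-1.1,-24.6,0,0
LBR,Liberia,21.2,11.2,-10.0,-47.2,37.9,12.3,-25.6,-67.6,0,0
MDG,Madagascar,25.7,10.7,-15.0,-58.5,34.0,17.1,-16.9,-49.8,0,0
MWI,Malawi,4.8,3.4,-1.4,-29.2,12.0,2.6,-9.4,-78.4,0,0
MLI,Mali,36.4,17.1,-19.3,-53.1,47.8,40.5,-7.3,-15.2,0,0
MRT,Mauritania,28.1,6.5,-21.6,-76.8,33.0,10.1,-22.8,-69.3,0,0
MOZ,Mozambique,12.7,3.6,-9.1,-71.8,23.5,7.6,-15.9,-67.5,0,0
MMR,Myanmar,11.5,17.6,6.1,52.9,25.4,13.7,-11.7,-46.0,0,0
NPL,Nepal,13.5,8.7,-4.7,-35.2,24.4,7.7,-16.7,-68.4,0,0
NER,Niger,52.6,18.2,-34.5,-65.4,23.5,20.4,-3.2,-13.4,0,0
NGA,Nigeria,55.5,28.9,-26.6,-48.0,71.7,64.9,-6.8,-9.5,0,0
PAK,Pakistan,24.0,8.4,-15.6,-65.1,37.2,36.5,-0.7,-2.0,0,0
PNG,Papua New Guinea,17.3,44.4,27.1,156.4,13.7,32.5,18.8,137.7,0,0
RWA,Rwanda,5.7,1.9,-3.8,-66.9,6.9,1.3,-5.6,-81.5,0,0
STP,Sao Tome and Principe,14.6,3.0,-11.6,-79.5,3.6,4.0,0.4,11.4,0,0
SEN,Senegal,17.3,2.2,-15.1,-87.1,23.9,9.9,-14.0,-58.4,0,0
SLE,Sierra Leone,31.1,9.0,-22.1,-71.0,30.5,7.5,-23.0,-75.4,0,0
SOM,Somalia,51.2,51.1,-0.1,-0.2,44.0,27.9,-16.1,-36.5,0,0
SSD,South Sudan,64.1,33.0,-31.1,-48.5,25.2,22.5,-2.7,-10.6,0,0
SDN,Sudan,33.1,3.4,-29.7,-89.6,14.4,4.8,-9.6,-66.9,0,0
TJK,Tajikistan,8.9,6.4,-2.5,-28.0,6.3,8.4,2.1,32.7,0,0
TZA,Tanzania,8.3,5.7,-2.7,-32.0,20.7,8.5,-12.2,-59.0,0,0
TLS,Timor-Leste,51.3,27.0,-24.3,-47.4,18.6,15.3,-3.3,-17.9,0,0
TGO,Togo,23.1,13.1,-10.1,-43.5,26.1,11.1,-15.0,-57.5,0,0
UGA,Uganda,21.9,6.7,-15.2,-69.2,29.2,6.3,-22.9,-78.5,0,0
UZB,Uzbekistan,1.3,7.2,5.9,441.9,2.9,5.1,2.2,77.5,0,0
VNM,Vietnam,7.8,4.6,-3.2,-41.0,17.3,8.7,-8.7,-50.0,0,0
YEM,Yemen,27.1,22.4,-4.7,-17.2,43.4,35.4,-8.1,-18.5,0,0
ZMB,Zambia,7.5,5.8,-1.7,-22.3,10.2,7.1,-3.1,-30.5,0,0
ZWE,Zimbabwe,20.1,5.5,-14.7,-72.9,19.5,6.6,-12.9,-66.0,0,0
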