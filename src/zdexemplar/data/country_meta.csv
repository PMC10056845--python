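country_code,name,income_group,gavi_supported,segmentation_group,learning_hub
AFG,Afghanistan,Low-income,1,Conflict/fragile,0
AGO,Angola,Lower-middle income,1,Core-ESA (Priority),0
BGD,Bangladesh,Lower-middle income,1,Core-Rest of World (Priority),1
BEN,Benin,Low-income,1,Core-WCA (Priority),0
BFA,Burkina Faso,Low-income,1,Core-WCA (Priority),0
BDI,Burundi,Low-income,1,Core-ESA (Standard),0
KHM,Cambodia,Lower-middle income,1,Core-Rest of World (Standard),0
CMR,Cameroon,Lower-middle income,1,Core-WCA (Priority),0
CAF,Central African Rep,Low-income,1,Conflict/fragile,0
TCD,Chad,Low-income,1,Conflict/fragile,0
COM,Comoros,Lower-middle income,1,Core-ESA (Standard),0
COG,Congo,Lower-middle income,1,Core-WCA (Priority),0
CIV,Cote d'Ivoire,Lower-middle income,1,Core-WCA (Priority),0
COD,Dem Rep of the Congo,Low-income,1,High impact,0
DJI,Djibouti,Lower-middle income,1,Core-ESA (Priority),0
ERI,Eritrea,Low-income,1,Core-ESA (Standard),0
ETH,Ethiopia,Low-income,1,High impact,0
GMB,Gambia,Low-income,1,Core-WCA (Standard),0
GHA,Ghana,Lower-middle income,1,Core-WCA (Priority),0
GIN,Guinea,Low-income,1,Core-WCA (Priority),0
GNB,Guinea-Bissau,Low-income,1,Core-WCA (Priority),0
HTI,Haiti,Low-income,1,Conflict/fragile,0
IND,India,Lower-middle income,1,High impact,0
KEN,Kenya,Lower-middle income,1,Core-ESA (Priority),0
KGZ,Kyrgyzstan,Lower-middle income,1,Core-Rest of World (Standard),0
LAO,Laos,Lower-middle income,1,Core-Rest of World (Priority),0
LSO,Lesotho,Lower-middle income,1,Core-ESA (Standard),0
LBR,Liberia,Low-income,1,Core-WCA (Standard),0
MDG,Madagascar,Low-income,1,Core-ESA (Priority),0
MWI,Malawi,Low-income,1,Core-ESA (Priority),0
MLI,Mali,Low-income,1,Conflict/fragile,1
MRT,Mauritania,Lower-middle income,1,Core-WCA (Standard),0
MOZ,Mozambique,Low-income,1,Core-ESA (Priority),0
MMR,Myanmar,Lower-middle income,1,Core-Rest of World (Priority),0
NPL,Nepal,Low-income,1,Core-Rest of World (Priority),0
NER,Niger,Low-income,1,Conflict/fragile,0
NGA,Nigeria,Lower-middle income,1,High impact,1
PAK,Pakistan,Lower-middle income,1,High impact,0
PNG,Papua New Guinea,Lower-middle income,1,Conflict/fragile,0
RWA,Rwanda,Low-income,1,Core-ESA (Standard),0
STP,Sao Tome and Principe,Lower-middle income,1,Core-WCA (Standard),0
SEN,Senegal,Lower-middle income,1,Core-WCA (Standard),0
SLE,Sierra Leone,Low-income,1,Core-WCA (Standard),0
SOM,Somalia,Low-income,1,Conflict/fragile,0
SSD,South Sudan,Low-income,1,Conflict/fragile,0
SDN,Sudan,Lower-middle income,1,Conflict/fragile,0
TJK,Tajikistan,Low-income,1,Core-Rest of World (Standard),0
TZA,Tanzania,Low-income,1,Core-ESA (Priority),0
TLS,Timor-Leste,Lower-middle income,1,Core-Rest of World (Standard),0
TGO,Togo,Low-income,1,Core-WCA (Priority),0
UGA,Uganda,Low-income,1,Core-ESA (Priority),1
UZB,Uzbekistan,Lower-middle income,1,Core-Rest of World (Standard),0
VNM,Vietnam,Lower-middle income,1,Core-Rest of World (Standard),0
YEM,Yemen,Low-income,1,Conflict/fragile,0
ZMB,Zambia,Lower-middle income,1,Core-ESA (Priority),0
ZWE,Zimbabwe,Lower-middle income,1,Core-ESA (Standard),0
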