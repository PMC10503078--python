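country_id,name,income_group,region,nha_year,gni_per_capita,gini,gini_source_year
AFG,Afghanistan,LI,South Asia,2014,558,,
BFA,Burkina Faso,LI,Sub-Saharan Africa,2016,602,47.3,2018
BDI,Burundi,LI,Sub-Saharan Africa,2013,230,38.6,2013
KHM,Cambodia,LI,East Asia & Pacific,2014,903,,
COD,"Congo, Democratic Republic of the",LI,Sub-Saharan Africa,2018,443,42.1,2012
ETH,Ethiopia,LI,Sub-Saharan Africa,2011,345,35.0,2015
GMB,"Gambia, Republic of the",LI,Sub-Saharan Africa,2015,549,35.9,2015
GIN,Guinea,LI,Sub-Saharan Africa,2014,655,29.6,2018
MWI,Malawi,LI,Sub-Saharan Africa,2015,310,38.5,2019
MLI,Mali,LI,Sub-Saharan Africa,2014,717,36.1,2018
MOZ,Mozambique,LI,Sub-Saharan Africa,2015,567,54.0,2014
NPL,Nepal,LI,South Asia,2016,779,32.8,2010
NER,Niger,LI,Sub-Saharan Africa,2015,496,37.3,2018
SLE,Sierra Leone,LI,Sub-Saharan Africa,2013,585,35.7,2018
TZA,Tanzania,LI,Sub-Saharan Africa,2015,868,40.5,2018
UGA,Uganda,LI,Sub-Saharan Africa,2016,709,42.8,2016
ZWE,Zimbabwe,LI,Sub-Saharan Africa,2010,620,50.3,2019
ARM,Armenia,LMI,Europe & Central Asia,2016,3330,32.5,2016
BEN,Benin,LMI,Sub-Saharan Africa,2013,1081,37.8,2018
CPV,Cabo Verde,LMI,Sub-Saharan Africa,2016,2772,42.4,2015
CMR,Cameroon,LMI,Sub-Saharan Africa,2011,1258,46.6,2014
COG,"Congo, Republic of the",LMI,Sub-Saharan Africa,2015,2746,48.9,2011
CIV,Côte d'Ivoire,LMI,Sub-Saharan Africa,2014,1789,37.2,2018
GHA,Ghana,LMI,Sub-Saharan Africa,2015,1718,43.5,2016
HTI,Haiti,LMI,Latin America & Caribbean,2014,1267,41.1,2012
KEN,Kenya,LMI,Sub-Saharan Africa,2016,1293,40.8,2015
LAO,Lao People's Democratic Republic,LMI,East Asia & Pacific,2012,1213,36.0,2012
MMR,Myanmar,LMI,East Asia & Pacific,2018,1081,30.7,2017
NGA,Nigeria,LMI,Sub-Saharan Africa,2016,2152,35.1,2018
WSM,Samoa,LMI,East Asia & Pacific,2015,3508,38.7,2013
STP,São Tomé & Príncipe,LMI,Sub-Saharan Africa,2013,1267,40.7,2017
SEN,Senegal,LMI,Sub-Saharan Africa,2013,1187,38.1,2018
TJK,Tajikistan,LMI,Europe & Central Asia,2013,1178,34.0,2015
VNM,Viet Nam,LMI,East Asia & Pacific,2015,2179,35.7,2018
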