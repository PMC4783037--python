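number,abbreviation,measure,unit,range,source,discrete
1,sedtrans,amount of sediment transported downstream per year,m^3/year,0–3000,expert,0
2,patchdiv-L,diversity of observed sediment patches,class 1 to 7,7–1,literature,1
3,sinuos,length of braids per river length,m/m,1–3,expert,0
4,depthveloc,Shannon Weaver diversity index of Froude numbers,number,0–1,expert,0
5,flowampl-F,maximal discharge,l/s,28000–4000,F,0
5,flowampl-BP,ratio high to low discharge per day,(m^3/s)/(m^3/s),8–0,BP,0
6,flowrate,rate of decrease of artificial flow,cm/hour,200–10,expert,0
7,dischav,% deviation of maximal discharge from reference river,%,100–0,expert,0
8,dischdist,% deviation of 5th percentile of discharge distribution from reference river,%,100–0,expert,0
9,flooddisch,% deviation of discharge of annual flood from reference river,%,100–0,expert,0
10,floodbed-BP,relative deviation of frequency of bed-moving floods from reference river,%,100–0,BP,0
10,floodbed-P,years between riverbed-forming discharges,HQ_xy,1–3 // 20–5,P,0
11,floodplain-BP,relative deviation of frequency of floodplain flooding from reference river,%,100–0,BP,0
11,floodplain-L,number of floodings per year,n°/year,0–1,literature,0
12,barrheight,height of artificial barrier,cm,100–0,expert,0
13,nopowerstat,number of power stations à 1 KW,n°,6–0,expert,0
14,ripbank,length of natural river banks per total length of both banks,m/m,0–1,expert,0
15,shorelength,length of the thalweg relative to the total length of both river banks,m/m,2–28,expert,0
16,leveeswidth,distance between levees compared to total floodplain width,m/m,0.05–1,expert,0
17,incision,depth of incision,m,5–0,expert,0
18,substrclog-L,class of substrate clogging,1 to 5,5–1,literature,1
19,substrarmor,relative values of sigma = sqrt (D16/D84),number,0–1,expert,0
20,hydrex,ratio of the observed vertical hydrological exchange between surface and ground water: exchange in a reference river,number,0.0001–1,expert,0
21,tempsummax,maximum water temperature in summer,°C,24–10,expert,0
22,tempav,maximum deviation of average water temperature compared to reference river,°C,15–0,expert,0
23,tempmax,highest water temperature recorded compared to temp. of reference river,°C,15–0,expert,0
25,amplday,deviation of daily amplitude from reference river,°C,20–0,expert,0
26,heatslope,difference between heating gradient of assessed and reference river,°C/hour,2–0,expert,0
27,cooslope,difference between cooling gradient of assessed and reference river,°C/hour,2–0,expert,0
28,sussolidtot-L,total suspended solids,mg/l,500–0,literature,0
29,sussolidlow,mean suspended solids concentration at low flow,g/m^3,No value function,expert,0
30,sussoliddep,solids´ deposition in floodplain,yes or no,0 or 1,expert,1
31,respirspr,in-stream respiration in spring,gO_2/m^2d,0–7 // 14–7,expert,0
32,prodspr,in-stream productivity in spring,gO_2/m^2d,0–2.5 // 10–2.5,expert,0
33,respirsu,in-stream respiration in summer,gO_2/m^2d,0–5 // 10–5,expert,0
34,prodsu,in-stream productivity in summer,gO_2/m^2d,0–0.5 // 10–0.5,expert,0
35,respirfa,in-stream respiration in fall,gO_2/m^2d,0–10 // 20–10,expert,0
36,prodfa,in-stream productivity in fall,gO_2/m^2d,0–0.5 // 10–0.5,expert,0
37,refug-BP,area with significant drop in temperature (max. temp.–temp. in certain spot),m^2,0–40,BP,0
37,refug-BB,area with significant drop in temperature (max. temp.–temp. in certain spot),m^2,0–50,BB,0
38,shorelength-BP,shoreline length per channel length,m/m,2–60,BP,0
38,shorelength-BB,shoreline length per channel length,m/m,2–17,BB,0
38,shorelength-BC,shoreline length per channel length,m/m,2–4,BC,0
39,tributar-BP,relative proportion of tributaries in a natural state,%,0–100,BP,0
39,tributar-BB,relative proportion of tributaries in a natural state,%,0–100,BB,0
39,tributar-BC,relative proportion of tributaries in a natural state,%,0–100,BC,0
40,structdiv,rel. proportion of area with deadwood per total river area,%,0–15 // 100–17,expert,0
41,driftbenthos,rel. proportion of benthos in drift compared to total benthos,%,10–2 // 0–1.5,expert,0
42,colm,rel. proportion of total interstitial space clogged with fine sediments,%,100–0,expert,0
43,softw-BP,area of softwood vegetation per wetted channel area per river length,proportion/m,0–5,BP,0
43,softw-BB,area of softwood vegetation per river length,m^2/m,0–40,BB,0
44,hardw,area of hardwood vegetation per wetted channel area per river length,proportion/m,0–6,expert,0
45,pionveg,area of pioneer vegetation per wetted channel area per river length,proportion/m,0–5,expert,0
46,gravel-BP,area of gravel bars per wetted channel area per river length,proportion/m,0–2,BP,0
46,gravel-BB,area of gravel bars per river length,%/m,0–100,BB,0
47,scrap,rel. proportion of scrapers in the macroinvertebrate community,%,0–30 // 100–30,expert,0
48,shred,rel. proportion of shredders in the macroinvertebrate community,%,0–20 // 40–20,expert,0
49,pred,rel. proportion of predators in the macroinvertebrate community,%,0–15,expert,0
50,collgath,rel. proportion of collector-gatherers in the macroinvertebrate community,%,0–20 // 50–20,expert,0
51,filter,rel. proportion of filterers in the macroinvertebrate community,%,0–20 // 100–20,expert,0
52,periph-BA,rel. proportion of periphyton,individuals/m^2,0–50 // 100–50,BA,0
52,periph-BB,amount of periphyton biomass per area,g ash free dry mass/m^2,0–100 // 200–100,BB,0
53,reti-index,Reti-index for macroinvertebrates: (scrapers + wood-eaters + shredders)/ all feeding types,number,0–50,expert,0
54,F13-index,F13 Yoshimura-index for macroinvertebrates: (scrapers + filterers)/ (shredders + gatherers-collectors),number,0.20–1.25,expert,0
55,shannonw,Shannon Weaver Index,number,0–4,expert,0
56,grbeetl,mean density of ground beetles,individuals/m^2,0–50,expert,0
57,rovbeetl,mean density of rove beetles,individuals/m^2,0–20,expert,0
58,totbiomasst,total biomass of trout,kg/ha,20–250,expert,0
59,YOYt,number of young-of-the-year (age-0 fish) trout,n° of ind.,"0–8,000",expert,0
60,juvent,number of juvenile (age-1 fish to sexual maturity) trout,n° of individuals,"0–3,000",expert,0
61,adbiomasst,total biomass of adult trout,kg/ha,0–150,expert,0
62,adbiomassb,total biomass of adult barbel and/or chub,kg/ha,0–80,expert,0
63,YOYb,number of young-of-the-year barbel,n° of ind.,"0–3,000",expert,0
64,juvenb,number of juvenile barbel and/or chub,n° of ind.,"0–3,000",expert,0
65,adultn,number of adult nase,n° of ind.,"0–2,000",expert,0
66,YOYn,number of young-of-the-year nase,yes or no,0–1,expert,1
67,totbiomasssp,total biomass of spirlin,kg/ha,0–30,expert,0
68,domin,dominance of any fish species,kg/ha,300–80,expert,0
69,nonsite,number of non-site-specific species,n° of species,10–0,expert,0
70,anom,percent fish with anomalies or injuries,%,50–0,expert,0
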