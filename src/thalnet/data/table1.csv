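# Clinical and demographic variables of the 12-patient thalamic RNS cohort (published per-patient table, transcribed verbatim).
case,age_years,gender,seizure_type,duration_years,followup_months,prior_resection,rns_target,laterality,cortical_target,engel
1,35,F,GTC,25,79,No,ANT,R,"Yes, R SMA",IA
2,48,M,GTC,24,43,No,ANT,B,No,IA
3,18,F,"Absence, FTBTC",13,38,No,ANT,B,No,IIB
4,34,F,"FIA, FTBTC",14,31,No,CM,B,No,IVA
5,20,M,"Absence, FTBTC",16.75,38,Yes,CM,B,No,IVC
6,16,M,FTBTC,10,35,No,ANT,B,No,IVA
7,22,M,FIA,6,29,No,CM,B,No,IIIA
8,18,M,GTC,3.83,67,No,CM,B,No,IIIA
9,25,M,FTBTC,8,39,No,CM,B,No,IA
10,22,F,FTBTC,11,31,No,CM,B,No,IIB
11,31,F,GTC,28,16,No,CM,B,No,IIIA
12,28,F,FTBTC,7,20,No,ANT,L,"Yes, L hippocampus",IVB
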