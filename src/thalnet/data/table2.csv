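# Imaging-analysis data of the 12-patient thalamic RNS cohort (published per-patient table, transcribed verbatim; polarity strings use ASCII '-').
case,soz_location,soz_roi_volumes_mm3,pattern,stim_setting,vta_volumes_mm3,n_streamlines_total,n_streamlines_activated,percent_activated,preop_per_month,postop_per_month,reduction_percent
1,R SMA,"3617, 4766",,R: 0+-0 .5,88R,10000,2883,29,0.17,0,100
2,R aCing,1360,,L: +-00 2 R: +-00 2,127L/128R,5000,798,16,0.33,0,100
3,"R OFC, R pIns, R mesT","7673, 8027, 2477",Transthalamic,L: 0+-0 2.9 R: +-00 2.9,248L/237R,13237,2015,15,750,4,95
4,"R OFC, R aIns","1302, 2188",Convergent,L: +-+- 3 R: +-+- 3,247L/245R,8846,447,5,4,3,25
5,"L&R pCing, L&R pIns","9360, 3751, 2427, 3658, 4158",Convergent,L: +-+- 4 R: +-+- 4,337L/340R,25000,1174,5,2,4,0
6,"R OFC, R mesT","2391, 2869",Transthalamic,L: +-+- 4 R: +-+- 4,332L/339R,10000,926,9,12,10,16.67
7,"R SMA, R aCing","3344, 2084",Convergent,L: +-+- 6 R: +-+- 6,745L/746R,10000,1936,19,2,0.8,60
8,L&R mPFC,"4410, 4094",,L: +-+- 4 R: +-+- 4,285L/282R,10000,1020,10,900,450,50
9,"L&R aCing, L pIns","3166, 3216, 3428",Convergent,L: +-00 1.5 R: 00+- 1.5,146L/100R,5150,805,16,3,0,100
10,"R mPFC, R SMA","4022, 2760",Convergent,L: +-00 3 R: 00+- 3,217L/250R,4721,1066,23,9,0.33,96.33
11,"L OFC, L aIns","1300, 2059",Convergent,L: +-+- 2.5 R: +-+- 2.5,227L/229R,10000,2557,26,4,1,75
12,L mesT,"1388, 1685, 1343",,L: +-+- 2,199L,15000,862,6,5,6,0
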