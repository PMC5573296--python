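space,tissue,region,side,mean_mm3,sd_mm3,cv_pct,pct_of_lobe
native,GMWM,SMG,L,28085,5578,20,23
native,GMWM,SMG,R,25530,5676,22,21
native,GM,SMG,L,14078,2697,19,24
native,GM,SMG,R,12765,2775,22,22
native,GMWM,AG,L,16109,4824,30,13
native,GMWM,AG,R,17444,4019,23,15
native,GM,AG,L,9844,2653,27,17
native,GM,AG,R,10564,2340,22,18
native,GMWM,postCG,L,31405,4080,13,26
native,GMWM,postCG,R,29278,3531,12,25
native,GM,postCG,L,12526,1856,15,17
native,GM,postCG,R,11725,1602,14,18
native,GMWM,supPL,L,46008,7978,17,38
native,GMWM,supPL,R,46736,7588,16,39
native,GM,supPL,L,22160,4116,19,38
native,GM,supPL,R,22619,3746,17,39
mni,GMWM,SMG,L,36194,4985,14,
mni,GMWM,SMG,R,33053,6138,19,
mni,GM,SMG,L,18172,2221,12,
mni,GM,SMG,R,16628,3070,18,
mni,GMWM,AG,L,20805,6346,31,
mni,GMWM,AG,R,22406,4714,21,
mni,GM,AG,L,12732,3497,27,
mni,GM,AG,R,13574,2657,20,
mni,GMWM,postCG,L,41071,3014,7,
mni,GMWM,postCG,R,38636,3609,9,
mni,GM,postCG,L,16409,1621,10,
mni,GM,postCG,R,15490,1832,12,
mni,GMWM,supPL,L,58793,5872,10,
mni,GMWM,supPL,R,59677,4985,8,
mni,GM,supPL,L,28333,3299,12,
mni,GM,supPL,R,28917,2606,9,
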