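code,region,side,manual_volume_mm3,auto_volume_mm3,jaccard_mean,jaccard_sd,jaccard_cv_pct,volume_error_pct
32,AG,L,16109,14956,0.58,0.09,16,0.23
33,AG,R,17444,16361,0.54,0.09,16,-0.84
60,postCG,L,31404,31342,0.72,0.07,9,0.08
61,postCG,R,29277,29031,0.71,0.05,7,-0.35
62,SupPL,L,46008,46456,0.77,0.05,7,2.25
63,SupPL,R,46735,47170,0.78,0.04,5,1.73
84,SMG,L,28091,27700,0.73,0.05,7,0.80
85,SMG,R,25541,24977,0.68,0.07,11,1.13
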