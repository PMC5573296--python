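subject_id,hemisphere,ips_continuous,ips_pcg_connected,smg_gmwm,smg_gm,sf_long,smg_sup,smg_inf,smg_top,smg_pct,smg_g_ant,smg_g_sup,smg_g_post,smg_g_total,pisj,ag_gmwm,ag_gm,as_long,ag_sup,ag_inf,ag_top,ag_pct,ag_g_ant,ag_g_sup,ag_g_post,ag_g_total,as_ips_connected
a01,L,0,1,39157,18225,1,42,82,57,63,1,0,2,3,3,32437,19572,1,38,82,50,73,1,1,1,3,0
a01,R,0,1,32559,16629,1,40,72,52,63,1,0,2,3,3,30152,17830,1,33,72,44,72,1,1,2,4,1
a02,L,0,1,42282,20162,1,34,82,46,75,1,1,1,3,3,17969,11313,1,43,82,53,74,0,1,1,2,0
a02,R,0,1,32177,15802,1,43,76,47,88,3,0,1,4,2,20010,12329,1,44,76,56,63,1,1,1,3,0
a03,L,1,1,35039,16605,1,43,75,55,63,0,1,1,2,3,17118,9572,1,45,75,59,53,1,0,1,2,0
a03,R,0,1,31168,14192,1,43,74,53,68,0,0,1,1,3,19302,11246,1,42,74,51,72,1,0,2,3,1
a04,L,0,0,44817,20723,0,42,84,68,38,2,2,0,4,3,17098,10689,1,45,84,49,90,0,0,0,0,0
a04,R,0,0,27739,12464,0,50,82,68,44,1,1,1,3,3,21988,12720,1,42,82,47,88,0,0,3,3,0
a05,L,0,1,44688,21519,1,40,82,57,60,1,2,1,4,2,10986,6993,1,44,82,61,55,0,2,0,2,0
a05,R,0,1,31155,15056,0,40,81,65,39,0,1,0,1,3,23757,13969,1,40,81,54,66,1,1,2,4,0
a06,L,1,1,35330,17709,1,42,85,61,56,1,1,0,2,1,19946,12585,1,45,85,52,77,1,0,1,2,0
a06,R,0,1,25839,12812,1,48,77,57,69,0,1,0,1,1,19653,12261,1,46,77,53,77,0,0,1,1,1
a07,L,1,1,29373,15083,1,45,79,61,53,0,0,1,1,3,33973,18512,1,43,79,49,83,0,1,1,2,0
a07,R,1,1,30777,14961,0,42,80,70,26,0,1,1,2,0,31273,18664,1,44,80,45,97,0,0,0,0,0
a08,L,1,1,37233,18839,1,43,80,59,57,1,1,1,3,3,12872,8255,1,46,80,61,56,2,1,0,3,0
a08,R,1,1,35181,17526,0,40,77,62,41,1,2,1,4,2,12450,8485,1,46,77,46,100,1,0,0,1,1
a09,L,0,1,35373,18637,1,42,85,58,63,1,1,1,3,2,21337,13480,1,38,85,52,70,1,1,1,3,1
a09,R,0,1,33915,17830,1,37,84,47,79,0,1,2,3,3,24381,15697,1,44,84,59,63,1,1,1,3,0
a10,L,1,1,36541,18920,0,43,80,66,38,2,2,0,4,1,17290,11671,1,43,80,55,68,2,1,0,3,0
a10,R,0,1,38738,19477,1,44,81,55,70,1,1,1,3,3,15883,10955,1,47,81,59,65,1,1,0,2,0
a11,L,0,1,25515,13321,1,51,86,63,66,0,1,1,2,3,15086,9423,1,57,86,63,79,2,0,0,2,1
a11,R,0,1,23774,12285,1,52,85,55,91,1,0,0,1,3,16764,10425,0,50,85,68,49,1,1,1,3,1
a12,L,1,1,32994,16382,1,40,78,56,58,0,2,1,3,3,19281,11978,1,43,78,47,89,0,0,2,2,0
a12,R,0,1,35232,17624,0,37,74,61,35,0,2,1,3,3,18340,11917,1,39,74,45,83,0,0,1,1,1
a13,L,1,1,33122,17020,1,42,77,46,89,1,1,0,2,2,13109,8424,1,45,77,51,81,1,0,0,1,0
a13,R,1,1,29997,15863,1,42,77,49,80,2,2,0,4,3,13206,8168,1,45,77,55,69,1,1,0,2,0
a14,L,1,1,29697,14249,0,46,78,63,47,1,1,0,2,3,17165,10456,1,48,78,56,73,2,0,0,2,0
a14,R,1,1,29784,15451,1,35,77,52,60,1,1,1,3,3,19663,11046,0,45,77,63,44,0,2,2,4,0
a15,L,0,0,28610,16234,0,42,73,59,45,1,1,0,2,3,18218,11806,1,41,73,43,94,0,0,0,0,1
a15,R,0,1,26872,14428,1,44,76,59,53,0,1,1,2,3,19207,11823,0,41,76,63,37,0,3,0,3,0
a16,L,1,1,33494,18404,1,42,83,56,66,2,2,0,4,1,28374,17192,1,44,83,59,62,3,0,0,3,0
a16,R,0,1,30277,15562,1,39,80,52,68,0,0,2,2,3,26112,16426,1,44,80,47,92,2,0,3,5,1
a17,L,0,1,29366,15255,1,39,73,43,88,1,0,1,2,2,30108,16963,1,34,73,42,79,1,1,2,4,0
a17,R,0,0,36487,20108,1,35,71,52,53,0,3,0,3,1,19811,12417,1,34,71,41,81,1,1,0,2,0
a18,L,0,0,42690,22667,0,35,80,63,38,2,1,0,3,2,20422,13389,1,41,80,48,82,0,0,1,1,0
a18,R,1,1,25302,13193,0,39,76,60,43,0,2,1,3,3,29599,18839,1,36,76,43,83,0,0,3,3,0
a19,L,1,1,35080,18404,1,59,91,63,88,2,0,1,3,3,20331,13024,1,52,91,61,77,1,1,1,3,0
a19,R,0,1,23203,12130,1,51,87,58,81,1,0,1,2,3,27358,16939,1,52,87,67,57,0,2,4,6,0
a20,L,0,0,43247,21644,1,40,83,51,74,3,0,0,3,3,22083,12292,1,35,83,45,79,0,1,0,1,1
a20,R,0,1,40274,19481,1,42,84,50,81,2,0,0,2,3,26123,14729,1,45,84,51,85,2,0,1,3,1
a21,L,0,1,38212,19528,1,42,81,59,56,0,2,0,2,3,20422,12893,1,40,81,53,68,0,1,0,1,0
a21,R,0,1,30058,14398,0,45,80,63,49,0,0,1,1,3,21809,13392,1,44,80,55,69,0,1,2,3,0
a22,L,0,1,41205,20189,0,42,85,73,28,1,2,0,3,3,26163,16325,1,50,85,56,83,0,0,2,2,0
a22,R,0,1,42927,20199,1,37,81,49,73,1,1,0,2,3,22397,13001,1,45,81,45,100,0,0,2,2,1
a23,L,1,1,32805,16804,1,48,89,62,66,0,2,1,3,2,28623,16521,1,45,89,55,77,2,0,1,3,0
a23,R,0,1,33490,16811,0,41,87,66,46,0,3,1,4,2,24428,15299,1,44,87,48,91,0,0,3,3,0
a24,L,1,1,42201,20267,1,44,83,54,74,0,1,2,3,3,21360,13129,1,50,83,59,73,1,0,0,1,0
a24,R,1,1,46079,22791,0,46,86,69,43,0,3,1,4,3,23298,13662,1,44,86,56,71,1,1,1,3,1
a25,L,1,1,33888,17000,1,46,81,51,86,2,0,0,2,3,30837,19389,1,42,81,56,64,0,2,1,3,1
a25,R,0,1,40129,20284,1,43,86,54,74,1,0,3,4,3,21425,13382,0,43,86,78,19,0,4,0,4,0
a26,L,1,1,34925,16963,1,51,90,54,92,0,0,0,0,3,29508,16939,1,49,90,52,93,0,0,4,4,0
a26,R,0,1,33396,18576,0,44,89,68,47,1,2,1,4,3,24030,13335,1,51,89,64,66,2,0,0,2,0
a27,L,0,1,36389,18043,0,45,80,65,43,1,2,1,4,2,13740,8539,1,49,80,55,81,0,0,1,1,0
a27,R,0,1,26264,13581,1,45,79,56,68,1,1,2,4,3,26926,14786,1,42,79,46,89,2,0,1,3,1
a28,L,0,1,35728,17250,0,55,89,73,47,0,2,0,2,2,15063,9781,1,58,89,64,81,0,0,2,2,1
a28,R,1,1,32650,16251,1,55,94,67,69,1,0,0,1,3,24192,14175,0,60,94,80,41,1,2,3,6,0
a29,L,1,1,37047,19369,1,44,83,52,79,0,1,2,3,1,18390,11576,1,51,83,54,91,0,0,1,1,0
a29,R,0,0,45313,23601,1,45,89,53,82,2,0,0,2,2,20183,13071,1,50,89,54,90,1,0,1,2,0
a30,L,1,1,39761,19754,0,48,87,69,46,2,2,0,4,2,14847,9295,1,54,87,70,52,0,1,0,1,0
a30,R,0,1,40821,19487,1,45,87,60,64,0,0,2,2,2,28451,16234,0,46,87,71,39,2,2,1,5,0
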