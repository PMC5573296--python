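subject_id,icv,brain,age,gender
a01,1250,1055,36,1
a02,1414,1177,26,0
a03,1386,1159,53,0
a04,1558,1309,38,0
a05,1629,1454,25,0
a06,1458,1218,33,0
a07,1284,1095,32,1
a08,1468,1281,23,0
a09,1325,1148,24,1
a10,1436,1286,20,0
a11,1428,1193,38,1
a12,1634,1401,36,0
a13,1424,1260,29,1
a14,1302,1093,54,1
a15,1269,1088,23,1
a16,1746,1474,29,0
a17,1379,1206,20,1
a18,1273,1141,26,1
a19,1533,1339,34,1
a20,1869,1569,32,0
a21,1458,1286,30,0
a22,1412,1222,29,1
a23,1531,1328,30,0
a24,1321,1153,32,1
a25,1351,1136,31,1
a26,1582,1356,33,0
a27,1400,1206,31,1
a28,1653,1358,30,0
a29,1693,1460,23,0
a30,1528,1306,31,1
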