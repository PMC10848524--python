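oligo,TriScale01,TriScale02,TriScale03,TriScale04,TriScale05,TriScale06,TriScale07,TriScale08,TriScale09,TriScale10,TriScale11,TriScale12
AAA,0.4655,-1.1974,0.5915,0.6527,0.5249,0.0916,0.1214,-0.9690,-1.4091,-1.2920,1.3149,0.8559
AAC,1.0993,1.0904,-0.1553,-0.4876,-0.6622,-0.7892,-1.5091,-0.9543,-1.4426,-0.7500,0.2617,-1.5695
AAG,0.3670,0.4251,-1.2796,-0.2795,0.3488,0.7469,-0.7630,1.2971,-0.9928,-1.2246,-0.6195,1.4874
AAT,-2.5528,0.5095,-0.4531,-1.0588,0.1158,0.2340,0.3533,0.9726,-0.4827,-0.0852,0.4916,-0.8542
ACA,1.3341,1.9789,0.1967,-0.2193,2.2467,-0.4633,0.0364,0.3963,-0.2100,0.5022,-0.5752,1.7520
ACC,-1.9822,-0.2161,0.2920,-0.8225,0.5473,-0.3397,1.0579,-0.5078,-0.2244,-0.4707,-0.1386,0.2805
ACG,0.7588,0.3240,1.6275,0.0929,-1.1690,1.5721,0.5663,-1.8820,2.1786,-1.1685,-0.5078,-0.9988
ACT,1.2311,0.2360,0.2753,0.2714,0.5798,-1.4154,1.0086,0.0527,-1.9401,-0.4442,1.5940,0.0522
AGA,-1.3074,-1.7780,0.3538,-0.0794,-0.3496,-1.2787,-0.4271,0.7722,-0.3468,0.7932,-0.7022,1.2298
AGC,-0.2176,0.5999,0.1197,-1.3174,0.3616,-1.7425,-0.7595,1.0825,-1.2100,1.1016,-1.0205,0.1852
AGG,-1.5882,-1.2588,-0.0499,0.1108,0.2692,-0.0106,1.6033,0.7030,-1.0120,-0.7834,-0.5513,0.3702
AGT,-1.4514,-0.3368,-0.5628,1.4013,-0.9780,1.7767,-1.4772,1.0454,-0.4028,-1.6208,0.0754,1.0908
ATA,0.3547,-1.1445,0.4401,0.5013,2.1168,0.0254,-1.5285,-1.1970,1.4676,-0.1993,-0.1787,-0.0295
ATC,-0.1702,0.7832,1.0479,-1.5357,-2.4302,0.3743,1.3395,-1.7679,0.5243,0.5622,-0.0367,0.1871
ATG,1.2105,0.0364,-0.2985,0.0648,0.8884,-1.0993,0.8198,1.3469,-1.0557,0.9006,-0.7622,-0.9668
ATT,-1.8003,0.2839,-2.6654,1.8393,-0.9709,0.3250,0.4684,0.2907,-0.5944,0.3141,-0.8962,0.1170
CAA,-0.8096,-0.7936,-0.3229,-1.1709,0.1134,-0.2940,1.5663,-0.6878,0.3561,-0.9109,0.1622,-0.8616
CAC,-0.5273,1.6442,-0.4507,-0.3337,-0.2206,-0.8890,-0.4805,2.2079,1.1515,2.3348,1.7257,1.6843
CAG,0.9911,0.0501,-1.4605,0.4338,-0.0644,-1.2450,1.3359,0.1128,-0.1188,0.0890,0.4516,0.1916
CAT,-0.1508,-0.1824,-1.0540,1.2510,0.4192,0.7379,0.4571,0.0911,0.9543,-0.2630,-0.6415,-1.1447
CCA,-1.3926,-0.3383,-0.4529,-2.8651,0.0504,-0.7519,1.5858,1.7652,-1.4956,0.2782,-1.8322,0.4462
CCC,-0.5123,1.1776,0.7485,-1.0579,0.2275,-1.5805,-0.9427,-1.2617,-0.5880,-1.0442,0.0559,-1.3165
CCG,1.0803,-0.6049,2.4181,1.0035,1.0799,1.6302,-0.2324,-0.3176,-0.1095,-1.7503,0.7898,-0.4293
CCT,1.1329,0.1210,-0.0011,1.2549,-0.2360,0.0905,-1.4535,0.6064,0.0970,-0.3963,0.8813,-0.9936
CGA,1.3332,-2.6752,-0.2642,1.2734,0.4025,-1.7035,0.6784,0.8635,0.3571,0.5882,0.6013,0.4668
CGC,-0.5183,-0.2310,-0.2460,-1.0596,-0.8772,0.1167,-0.3265,0.1161,-1.1015,2.5330,-0.9107,1.3777
CGG,-0.5813,0.1301,1.8058,-2.1385,-0.3353,-0.2834,1.1095,0.8847,1.0778,-0.2938,0.2700,2.5433
CGT,1.0048,0.3083,0.2032,0.1871,-0.8278,-0.8114,-1.8168,0.7333,1.2789,0.7222,1.6611,-0.8318
CTA,1.4472,1.5660,-1.3636,-0.4347,1.0107,1.9861,-0.0882,0.8964,1.2618,-0.7275,-1.6252,0.1684
CTC,-0.0993,0.4331,0.2659,0.6243,0.7337,-0.9940,0.4863,-0.4031,-0.9146,-0.6069,-0.8215,1.0345
CTG,-0.6066,0.4922,0.7392,-0.8559,0.1026,0.0053,-0.0051,-0.7069,-0.6300,-0.8300,-0.1612,1.2051
CTT,0.0551,0.0578,1.0517,0.2557,-0.4087,1.0441,-0.1218,0.0061,-0.5919,1.2816,-0.5106,1.2387
GAA,0.6219,-0.0868,0.5657,0.5220,-2.3697,-0.0800,-1.8893,-0.2914,-0.4787,-0.5263,-0.0557,0.6828
GAC,0.2532,-0.5187,0.9482,-1.2672,-1.0054,2.3204,-0.0959,-1.3911,0.0750,2.3895,-0.4589,-0.8134
GAG,0.5112,-0.2677,-0.5987,-1.6177,2.6136,2.0853,-0.9335,-2.0040,0.1677,-0.0699,1.2901,0.2473
GAT,-0.8012,-1.6467,-2.2875,-0.3103,1.5688,-0.6789,-0.3600,1.6449,1.5836,-1.5356,0.2730,-0.4599
GCA,0.9524,-1.4655,-0.4124,-0.3387,0.3772,1.0655,0.8414,-0.7695,-0.3832,-1.5401,0.4711,-1.1349
GCC,-0.2026,0.9667,-1.6180,3.0212,-0.4348,-0.7266,-1.0485,-0.0758,1.5379,0.4928,-1.2510,-0.0897
GCG,-0.8494,0.7386,-0.7761,0.5009,-1.0536,0.2079,-1.9323,-0.4265,1.1680,0.9111,1.4656,-0.3327
GCT,-0.1350,-0.6570,0.4786,0.3334,1.4766,-0.9200,-0.0137,2.3169,1.1946,1.7548,-1.6599,0.0533
GGA,0.6627,-0.1585,0.8217,-0.0899,0.7457,0.9920,0.6007,1.0917,-0.3437,0.3142,0.8504,-1.8318
GGC,0.0668,1.8648,-0.9740,-0.3821,-0.0484,-0.8246,0.5591,0.2836,-0.2247,0.5641,-0.8705,-0.6470
GGG,0.6112,-0.9598,-0.8251,0.0109,-0.6582,0.6040,1.3036,-0.5017,-0.6342,0.4797,-0.8478,1.0271
GGT,-0.1849,1.7286,0.4097,0.4214,1.0998,-0.5689,-1.4294,0.4936,1.6490,0.7760,0.8434,1.2192
GTA,-0.0265,0.0405,-1.6765,0.7951,-2.0257,-1.2974,0.5958,-1.7311,0.3546,-0.6942,1.0848,-0.7534
GTC,-0.1708,0.2248,-0.9660,-0.3186,0.3922,-0.5283,1.0806,0.3776,1.7857,0.2695,-0.0625,-0.9714
GTG,-0.1636,0.6882,0.9920,0.3520,-0.5579,0.8010,2.1591,-0.7567,-0.5586,-0.2989,-1.3514,0.3817
GTT,0.0244,1.0982,1.1534,0.5639,-0.1542,1.2775,0.2962,-1.2351,-0.8056,-0.2574,-1.4901,-0.4202
TAA,1.4657,0.9762,-0.3032,0.8184,0.0462,0.4591,-0.5909,-0.3971,0.0648,0.6492,1.4163,1.7890
TAC,-1.0514,-0.5395,1.5556,0.0864,1.3192,1.6616,0.7706,-1.5498,1.6955,0.3670,-1.0185,0.0118
TAG,-0.2352,0.2434,0.1910,1.0990,-1.8549,0.6435,-1.9079,-0.0616,-1.4421,-1.2205,0.1343,0.4562
TAT,-0.2218,-0.3978,1.5298,-0.9844,0.0073,0.6561,0.1006,-0.8908,-2.0192,-0.4686,1.0516,-2.1727
TCA,0.0987,-1.0361,1.1626,1.3361,-1.2113,-0.1205,0.5837,-2.0326,-0.8924,-1.9607,0.5266,-0.7859
TCC,-0.1958,1.5554,1.9536,0.3521,-1.3269,0.6042,-0.4583,0.9243,-0.3214,0.5469,-0.4358,1.0104
TCG,1.9730,-0.3284,0.8883,-0.4001,0.1908,-1.3209,-0.3998,0.3976,-0.1249,-0.4824,-0.6109,-1.0305
TCT,0.1189,-0.9600,-0.5476,-0.9374,0.4244,0.9182,0.5236,-0.2638,1.3838,0.0029,-0.2546,-0.3945
TGA,0.3273,2.1791,-0.2405,-0.8903,-0.3570,-0.3527,0.0324,-0.4032,1.4304,-0.2659,1.1197,-0.3412
TGC,0.1219,-0.4430,0.4632,0.0781,0.3074,-0.0980,-0.7778,0.3537,0.0874,-0.2084,-2.5850,-0.0755
TGG,1.0562,0.4298,-0.9938,1.1204,0.9788,-0.9838,-0.4800,-0.1467,-0.4934,-0.7899,-0.9923,-1.8414
TGT,-0.5227,-0.0534,-0.5440,0.5201,-0.5202,0.1872,-0.3339,-0.1178,-0.3640,2.0602,0.2115,-0.1155
TTA,-0.4189,-1.4083,-0.4669,-0.8022,0.1809,0.2565,-0.5016,0.2883,0.3269,-0.4096,1.4134,-0.8057
TTC,2.0213,-1.3197,0.2363,-0.2690,0.5724,-1.4527,-0.1657,0.1326,0.6888,0.7540,0.4545,0.3341
TTG,-2.6323,-1.7207,-0.3464,-0.5317,-0.4992,-0.5747,2.0290,0.3476,-0.5308,1.1512,1.8803,-1.1356
TTT,-0.6725,-0.2573,-0.8692,1.7067,-0.8337,0.7227,-0.8200,0.8065,0.5911,0.1058,1.6132,0.9713
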