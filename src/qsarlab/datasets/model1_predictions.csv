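compound_id,pic50,y_pred_printed,residual_printed,set
1,4.3202,4.3219,-0.0017,train
2,4.9846,4.7403,0.2443,train
3,4.8011,4.6737,0.1274,train
4,5.0262,5.0411,0.0209,train
5,4.0206,4.2734,-0.2529,train
6,4.6407,4.7065,-0.0658,test
7,4.0286,4.5857,-0.5571,test
8,4.5252,4.4381,0.0871,test
9,4.0543,4.1766,-0.1223,train
10,4.0434,4.1436,-0.1002,train
11,4.2142,4.5352,-0.3210,train
12,4.4309,4.0666,0.3643,train
13,4.4865,4.4213,0.0652,train
14,4.4026,4.2774,0.1252,train
15,4.0829,4.1101,-0.0272,train
16,4.9000,4.8921,0.0079,train
17,4.8133,4.8557,-0.0424,train
18,4.7247,4.9270,-0.2023,train
19,4.5607,4.3625,0.1982,train
20,4.3428,4.1947,0.1481,train
21,4.1388,4.4897,-0.3509,train
22,4.9311,4.9916,-0.0605,train
23,5.1203,4.9935,0.1268,test
24,5.1062,4.9494,0.1568,test
25,4.6955,4.7353,-0.0398,train
26,5.0132,4.6610,0.3522,train
27,5.2027,4.7426,0.4601,test
28,5.0232,4.7887,0.2345,train
29,4.6269,4.7330,-0.1061,train
30,4.8645,4.7518,0.1127,train
31,4.3002,4.3924,-0.0922,train
32,4.0947,4.3760,-0.2813,train
33,4.5882,4.4399,0.1483,test
34,4.5508,4.5509,-0.0005,train
35,4.2447,4.2702,-0.0255,test
36,4.7537,4.6338,0.1199,test
37,4.5769,4.6078,-0.0309,test
38,4.4583,4.3050,0.1533,test
39,4.6570,4.3798,0.2773,test
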