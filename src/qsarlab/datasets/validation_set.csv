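compound_id,pic50,MATS4e,GATS5e,SpMax4_Bhs,RDF150u,y_pred_printed
23,5.1203,-0.1068,0.8685,3.9563,5.5912,4.9935
24,5.1062,-0.1214,0.8301,3.9563,4.7605,4.9494
27,5.2027,-0.1666,0.9511,3.8468,6.6068,4.7426
33,4.5882,-0.1687,0.8792,3.8317,0.8057,4.4399
35,4.2447,-0.1646,0.9304,3.8245,0.0040,4.2702
36,4.7537,-0.1093,0.8139,3.9606,1.24e-28,4.6337
37,4.5769,-0.1197,0.8164,3.9607,0.3669,4.6078
38,4.4583,-0.1590,0.9474,3.7874,1.90e-17,4.3050
39,4.6570,-0.1725,0.9504,3.7880,1.6951,4.3798
6,4.6407,-0.1135,0.7806,3.9553,4.89e-47,4.7065
7,4.0286,-0.1231,0.8095,3.9553,2.53e-33,4.5857
8,4.5252,-0.1680,0.8066,3.9661,0.9960,4.4381
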