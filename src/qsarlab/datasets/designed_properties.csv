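compound_id,MW,nAH,nRB,HBA,HBD,MR,TPSA,iLOGP,BBB,PAINS,Brenk
1,415.24,17,3,4,0,114.80,45.81,3.81,Yes,1,2
2,415.24,17,3,4,0,114.80,45.81,3.72,Yes,1,2
3,504.15,17,3,4,0,120.18,45.81,3.93,Yes,1,1
4,382.34,17,3,6,0,104.69,45.81,3.52,Yes,1,1
5,415.24,17,3,4,0,114.80,45.81,3.70,Yes,1,1
6,415.24,17,3,4,0,114.80,45.81,3.72,Yes,1,2
7,504.15,17,3,4,0,120.18,45.81,3.80,Yes,1,2
8,490.12,17,3,4,0,115.21,45.81,3.51,Yes,1,1
9,401.22,17,3,4,0,109.83,45.81,3.49,Yes,1,2
10,490.12,17,3,4,0,115.21,45.81,3.51,Yes,1,1
11,490.12,17,3,4,0,115.21,45.81,3.74,Yes,1,2
12,401.22,17,3,4,0,109.83,45.81,3.35,Yes,1,1
13,490.12,17,3,4,0,115.21,45.81,3.70,Yes,1,2
14,401.22,17,3,4,0,109.83,45.81,3.49,Yes,1,2
15,472.25,17,3,4,0,117.49,45.81,3.67,Yes,1,2
16,425.25,17,3,4,0,112.48,45.81,3.76,Yes,1,1
17,380.80,17,3,4,0,109.79,45.81,3.72,Yes,1,1
18,366.77,17,3,4,0,104.82,45.81,3.29,Yes,1,1
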