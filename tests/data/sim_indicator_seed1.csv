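V1,V2,V3,V4,group
1.0,1.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,0.0,1.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
0.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,1.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
0.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,1.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,1.0,1.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,1.0,G1
1.0,0.0,0.0,0.0,G1
0.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,0.0,0.0,0.0,G1
1.0,1.0,0.0,1.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,1.0,0.0,G2
0.0,0.0,1.0,0.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,0.0,1.0,G2
0.0,0.0,1.0,1.0,G2
0.0,0.0,1.0,1.0,G2
0.0,1.0,0.0,0.0,G2
0.0,1.0,1.0,0.0,G2
1.0,0.0,0.0,1.0,G2
0.0,1.0,0.0,1.0,G2
0.0,0.0,1.0,0.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,0.0,0.0,G2
0.0,0.0,1.0,1.0,G2
0.0,0.0,0.0,1.0,G2
0.0,1.0,0.0,0.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,1.0,1.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,1.0,1.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,0.0,0.0,G2
0.0,1.0,1.0,1.0,G2
0.0,1.0,0.0,1.0,G2
0.0,0.0,0.0,1.0,G2
0.0,1.0,0.0,1.0,G2
0.0,0.0,0.0,0.0,G2
0.0,0.0,0.0,0.0,G2
0.0,1.0,1.0,1.0,G2
0.0,0.0,1.0,1.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,0.0,0.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,1.0,0.0,G2
0.0,0.0,1.0,0.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,0.0,0.0,G2
0.0,1.0,0.0,1.0,G2
0.0,1.0,1.0,1.0,G2
0.0,1.0,1.0,1.0,G2
0.0,0.0,1.0,1.0,G2
0.0,1.0,1.0,0.0,G2
0.0,1.0,0.0,1.0,G2
0.0,0.0,1.0,1.0,G3
0.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
0.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
0.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
0.0,1.0,1.0,1.0,G3
0.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
0.0,0.0,0.0,0.0,G3
0.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
0.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
0.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
0.0,0.0,1.0,0.0,G3
1.0,0.0,1.0,1.0,G3
0.0,0.0,1.0,0.0,G3
0.0,0.0,0.0,0.0,G3
1.0,0.0,1.0,1.0,G3
1.0,1.0,1.0,1.0,G3
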