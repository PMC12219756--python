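time_min,depth_mm
0,15.0
10,14.5
20,13.0
30,9.5
40,4.0
50,1.0
60,0.0
70,0.0
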