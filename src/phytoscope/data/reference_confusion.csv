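class,det,ukw,1,2,3,4,5,6,7,8,9,10
det,11061,0,0,1,0,0,0,0,0,0,0,0
ukw,0,371,0,2,0,4,3,0,7,3,0,13
1,0,3,91,0,0,0,0,0,1,0,1,0
2,0,5,3,182,0,0,0,0,2,0,0,1
3,0,1,0,0,57,1,1,0,0,0,0,0
4,0,0,0,2,0,115,0,0,0,0,0,0
5,0,1,0,0,0,0,124,2,8,3,0,0
6,0,7,0,2,0,0,0,94,0,0,1,0
7,0,2,1,0,0,0,0,0,253,2,1,2
8,0,0,0,0,0,0,0,0,0,59,3,0
9,0,1,0,0,0,5,0,0,0,0,127,0
10,0,10,2,0,0,0,1,0,1,0,0,240
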