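value,count
1,449
2,232
3,131
4,79
5,40
6,15
7,5
8,3
9,1
10,2
11,0
12,0
13,1
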