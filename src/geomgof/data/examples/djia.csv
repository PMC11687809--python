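value,count
1,518
2,262
3,116
4,60
5,30
6,13
7,12
8,4
9,2
10,1
11,0
12,1
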