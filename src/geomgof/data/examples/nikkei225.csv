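value,count
1,502
2,258
3,118
4,66
5,19
6,13
7,7
8,5
9,2
10,1
11,0
12,1
13,1
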