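value,count
1,539
2,253
3,121
4,56
5,36
6,9
7,8
8,4
9,2
10,2
11,2
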