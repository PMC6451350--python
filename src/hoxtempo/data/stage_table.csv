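hpf,stage
3,7
4.5,9
6.5,10
7.5,10~10.5
8.5,11~11.5
9.5,12
10.5,12.5
11.5,13
12.5,15
13.5,17
14.5,18
16.5,21
18.5,23
19.5,24
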