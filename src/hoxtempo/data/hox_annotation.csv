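gene_id,cluster,paralogous_group
hoxa1,A,1
hoxa2,A,2
hoxa3,A,3
hoxa4,A,4
hoxa5,A,5
hoxa6,A,6
hoxa7,A,7
hoxa9,A,9
hoxa10,A,10
hoxa11,A,11
hoxa13,A,13
hoxb1,B,1
hoxb2,B,2
hoxb3,B,3
hoxb4,B,4
hoxb5,B,5
hoxb6,B,6
hoxb7,B,7
hoxb8,B,8
hoxb9,B,9
hoxc3,C,3
hoxc4,C,4
hoxc5,C,5
hoxc6,C,6
hoxc8,C,8
hoxc9,C,9
hoxc10,C,10
hoxc11,C,11
hoxc12,C,12
hoxc13,C,13
hoxd1,D,1
hoxd3,D,3
hoxd4,D,4
hoxd8,D,8
hoxd9,D,9
hoxd10,D,10
hoxd11,D,11
hoxd13,D,13
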