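cluster	modality	members	columns
1	visual	1,23,2,5,22,9
2	somatomotor	20,21
3	somatomotor	4,7,18
4	auditory	14,25,27,32,17
5	association	24,13,29,28,30,11,19,31,26,16
6	association	3,15
7	association	6,8
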