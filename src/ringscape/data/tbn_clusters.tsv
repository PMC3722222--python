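cluster	modality	members	columns
1	visual	2,5,22,9
2	somatomotor	20,7,18,21
3	somatomotor	4
4	auditory	14,25
5	auditory	32,17,27
6	association	6,1,23,24,13,29,3,28,30,11,19,31,26,8,16,15
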