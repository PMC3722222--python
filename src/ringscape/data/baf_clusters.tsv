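cluster	modality	members	columns
1	visual	2,22,9,5	BAF7
2	somatomotor	4,7,21	BAF6
3	somatomotor	18	BAF6,BAF7
4	somatomotor	20	BAF6,BAF5
5	auditory	25,14,17,32	BAF5
6	association	27,28,11,29,13,19,6,26,18,20,8,24	BAF1,BAF2,BAF3,BAF4
7	association	3,15,30,16	BAF4
8	association	31	BAF2
9	association	23	BAF3
10	association	1	BAF1
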