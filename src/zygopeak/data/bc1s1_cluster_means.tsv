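population	n_homozygous	homozygous_height	homozygous_area	n_hemizygous	hemizygous_height	hemizygous_area	ccc
Coker312	57	678.2	4426.7	103	344.4	2315.4	3.57
DP90	50	766.6	4587.8	108	389.7	2556.1	7.32
SG747	58	757.7	4271.2	113	394.0	2471.4	8.31
PSC355	52	796.7	5177.6	110	405.6	2676.8	4.22
FM966	64	760.0	5296.2	110	395.4	2868.4	7.76
UA222	62	788.6	5461.5	108	414.2	3044.1	4.63
TAM B182-33	63	740.1	4961.6	116	405.4	2885.3	2.02
MD51ne	66	862.3	3018.0	115	436.7	3190.3	6.93
MD90ne	55	910.9	6440.9	104	469.2	3390.7	8.26
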