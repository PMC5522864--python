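population	n_transgenic	n_null	n_missing	n_total
Coker312	160	68	12	240
DP90	158	66	16	240
SG747	171	48	21	240
PSC355	162	56	22	240
FM966	174	60	6	240
UA222	170	66	4	240
TAM B182-33	179	56	5	240
MD51ne	181	49	10	240
MD90ne	159	58	23	240
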