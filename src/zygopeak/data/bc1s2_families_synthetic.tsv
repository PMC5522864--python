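family_id	parent_prediction	n_homozygous	n_hemizygous	n_null
H01	homozygous	23	0	0
H02	homozygous	23	0	0
H03	homozygous	23	0	0
H04	homozygous	23	0	0
H05	homozygous	23	0	0
H06	homozygous	23	0	0
H07	homozygous	23	0	0
H08	homozygous	23	0	0
H09	homozygous	23	0	0
H10	homozygous	23	0	0
H11	homozygous	23	0	0
H12	homozygous	23	0	0
H13	homozygous	23	0	0
H14	homozygous	23	0	0
H15	homozygous	22	0	0
H16	homozygous	22	0	0
H17	homozygous	22	0	0
H18	homozygous	24	0	0
H19	homozygous	21	0	0
H20	homozygous	6	12	5
E01	hemizygous	5	12	6
E02	hemizygous	6	11	6
E03	hemizygous	6	12	5
E04	hemizygous	5	11	7
E05	hemizygous	7	11	5
E06	hemizygous	6	10	7
E07	hemizygous	4	12	7
E08	hemizygous	7	12	4
E09	hemizygous	5	13	5
E10	hemizygous	6	12	5
E11	hemizygous	5	12	6
E12	hemizygous	6	11	6
E13	hemizygous	7	10	6
E14	hemizygous	4	13	6
E15	hemizygous	6	13	5
E16	hemizygous	5	10	8
E17	hemizygous	6	12	6
E18	hemizygous	7	12	5
E19	hemizygous	5	13	6
E20	hemizygous	6	11	7
E21	hemizygous	5	13	5
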