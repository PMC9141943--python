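accession	description	peptides	RL09 GAL	RL10 GAL	RL10 GLU	RL10 GLY	printed_log2r1	printed_log2r2
A0A4Q0LMV5	Amylopullulanase	64	2.8e5	2.5e7	7.5e5	1.8e7	6.5	4.6
A0A135Z5X6	Cell surface protein	11	1.5e6	3.2e6	1.2e6	3.2e6	1.1	1.4
D5GXS8	Lysin (Glycoside Hydrolase Family)	10	2.9e5	3.6e5	4.0e5	9.7e5	0.3	1.3
D5H1Q3	Aggregation promoting factor	4	ND	ND	1.5e5	2.2e5	ND	0.6
A0A135ZFI7	N-acetylmuramidase	17	1.3e6	2.0e6	4.0e6	4.1e6	0.6	0.04
K1MET7	Uncharacterized protein	29	6.4e6	1.0e7	7.6e6	2.3e6	0.7	0.04
A0A6M1GK10	S-layer protein (Fragment)	32	4.2e5	6.9e5	3.0e5	3.0e5	0.7	-0.02
C7XI68	SlpA domain-containing protein	14	3.2e5	7.3e5	6.4e5	6.1e5	1.2	-0.07
A0A6B8SPR2	SlpA domain-containing protein	15	3.1e7	2.2e7	1.3e7	1.1e7	-0.5	-0.2
A0A135ZF64	Amidase	10	5.7e5	1.7e6	1.7e6	1.4e6	1.6	-0.2
A0A135ZH73	Lysin	11	4.5e6	8.8e6	6.6e6	5.6e6	1.0	-0.2
A0A7V8KTK5	Putative surface layer protein	48	1.6e7	2.8e6	2.7e7	2.2e7	0.8	-0.3
E3R4X6	Uncharacterized protein	9	2.6e6	2.8e6	2.7e6	2.3e6	0.1	-0.3
K1MJV3	Uncharacterized protein	22	1.6e7	2.9e7	2.0e7	1.6e7	0.8	-0.3
V5EI62	Lysin (Glycoside Hydrolase Family)	15	2.4e6	4.6e6	1.1e7	7.6e6	0.9	-0.5
V5EF53	SlpA domain-containing protein	12	2.1e7	3.0e7	6.1e7	4.3e7	0.5	-0.5
A0A4Q0LUE2	Uncharacterized protein	24	2.7e7	1.8e7	3.3e7	2.3e7	-0.6	-0.5
A0A4R6CSS1	Cell surface protein (SlpA)	21	2.4e6	5.8e6	6.6e6	4.6e6	1.3	-0.5
D0DJ09	Bacterial surface layer protein	45	3.6e8	4.8e8	5.1e8	3.5e8	0.4	-0.5
K1M186	Uncharacterized protein	12	8.0e6	9.7e6	9.5e6	6.1e6	0.3	-0.6
A0A135YZ62	Bacterial surface layer protein (SlpA)	32	2.0e7	3.3e7	8.7e7	5.5e7	0.8	-0.6
D0DIV9	Uncharacterized protein	36	5.3e7	7.6e7	1.3e8	7.9e7	0.5	-0.7
V5GA31	Lactocepin s-layer protein	10	1.8e6	2.7e6	8.4e6	3.2e6	0.6	-1.4
A0A120DHV3	Uncharacterized protein	16	6.0e6	1.1e7	2.1e7	7.7e6	0.8	-1.4
K1N369	Uncharacterized protein	8	9.8e4	3.7e4	1.4e5	3.0e4	-1.4	-2.2
A0A125P6L8	S-layer protein (SlpA)	13	1.1e4	1.3e5	8.7e5	4.2e3	3.5	-7.7
A0A7T1TNA6	Bacterial surface layer protein	30	4.7e6	5.7e6	6.1e7	2.5e5	0.3	-7.9
A0A1C2D5C0	Cell surface protein	5	ND	1.5e6	8.1e5	ND	ND	ND
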