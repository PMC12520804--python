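# Published mt-tRNA variant screening table: 43 substitutions in 302 cases
# (PCOS with insulin resistance) vs 589 controls.  Transcribed as printed;
# numbering follows mitotRNAdb, arrows mark Watson-Crick pairs created (↑)
# or disrupted (↓), p from chi-square on the carrier counts.
gene	mutation	ci_percent	element	numbering	wc	case_carriers	case_percent	control_carriers	control_percent	p	previously_reported
tRNA-Phe	596T>C	43.9	D-arm	20		1	0.33	0	0	0.16	Yes
tRNA-Phe	634T>C	17.1	TψC loop	58		0	0	1	0.17	0.47	Yes
tRNA-Val	1658T>C	51.2	TψC loop	61		1	0.33	0	0	0.16	Yes
tRNA-Leu(UUR)	3302A>G	96.1	Acceptor arm	71	T-A↓	1	0.33	0	0	0.16	Yes
tRNA-Leu(UUR)	3275C>T	86.6	Variable region	44	A-T↑	1	0.33	0	0	0.16	Yes
tRNA-Leu(UUR)	3290T>C	31.2	TψC loop	59		3	1.0	3	0.51	0.40	Yes
tRNA-Ile	4277T>C	21.2	D-arm	15		0	0	1	0.17	0.47	Yes
tRNA-Ile	4312C>T	19.5	TψC loop	54		1	0.33	0	0	0.16	Yes
tRNA-Met	4454T>C	60.0	TψC loop	58		0	0	3	0.51	0.21	Yes
tRNA-Gln	4363T>C	75.0	Anticodon stem	38		1	0.33	0	0	0.16	Yes
tRNA-Gln	4395T>C	57.1	Acceptor arm	6	C-G↑	1	0.33	0	0	0.16	Yes
tRNA-Trp	5531A>G	24.4	D-arm	20		1	0.33	1	0.17	0.63	Yes
tRNA-Trp	5567T>C	68.3	TψC loop	61		1	0.33	1	0.17	0.63	Yes
tRNA-Ala	5601C>T	63.4	TψC loop	59		2	0.66	3	0.51	0.77	Yes
tRNA-Ala	5603G>A	70	TψC loop	61		1	0.33	3	0.51	0.70	Yes
tRNA-Asn	5711A>G	65.6	D-arm	19		1	0.33	0	0	0.16	Yes
tRNA-Cys	5802G>A	100	Anticodon stem	30	G-C↓	1	0.33	0	0	0.16	Yes
tRNA-Cys	5811T>C	67.0	D-arm	16		1	0.33	2	0.34	0.98	Yes
tRNA-Cys	5821G>A	66.6	Acceptor arm	6	G-C↓	3	0.99	1	0.17	0.08	Yes
tRNA-Ser(UCN)	7492C>T	73.1	Anticodon stem	26	A-T↑	1	0.33	0	0	0.16	Yes
tRNA-Ser(UCN)	7498C>T	33.0	D-arm	17		0	0	2	0.34	0.31	Yes
tRNA-Asp	7543A>G	73.3	Anticodon stem	29	A-T↓	1	0.33	0	0	0.16	Yes
tRNA-Asp	7544C>T	100	Anticodon stem	30	C-G↓	2	0.66	0	0	0.048	No
tRNA-Lys	8343A>G	46.1	TψC loop	54		4	1.32	2	0.34	0.09	Yes
tRNA-Gly	10007T>C	43.8	D-arm	20		0	0	1	0.17	0.47	Yes
tRNA-Gly	10031T>C	51.2	Variable region	44		3	1.0	2	0.34	0.98	Yes
tRNA-Gly	10039A>G	58.5	TψC loop	53		0	0	2	0.34	0.31	Yes
tRNA-Arg	10454T>C	69.2	TψC loop	55		1	0.33	3	0.51	0.71	Yes
tRNA-His	12153C>T	59.0	D-arm	16		1	0.33	1	0.17	0.63	Yes
tRNA-His	12188T>C	63.4	TψC loop	55		1	0.33	0	0	0.16	Yes
tRNA-His	12189T>C	36.5	TψC loop	56		0	0	4	0.68	0.15	Yes
tRNA-Ser(AGY)	12234A>G	70.7	Acceptor arm	42		2	0.66	2	0.34	0.49	Yes
tRNA-Ser(AGY)	12246C>A	50.0	TψC loop	54		1	0.33	0	0	0.16	Yes
tRNA-Leu(CUN)	12280A>G	58.5	D-arm	15		1	0.33	1	0.17	0.63	Yes
tRNA-Glu	14693A>G	100	TψC loop	54		3	0.99	3	0.51	0.40	Yes
tRNA-Glu	14727T>C	43.9	D-arm	18		0	0	1	0.17	0.47	Yes
tRNA-Thr	15900T>C	46.6	D-arm	13		0	0	1	0.17	0.47	Yes
tRNA-Thr	15904C>T	67.3	D-arm	17		0	0	2	0.34	0.31	Yes
tRNA-Thr	15907A>G	63.4	D-arm	22		1	0.33	0	0	0.16	Yes
tRNA-Thr	15930G>A	12.5	Variable region	45		0	0	3	0.51	0.21	Yes
tRNA-Thr	15938C>T	41.4	TψC loop	54		0	0	1	0.17	0.47	Yes
tRNA-Pro	15970T>C	24.4	TψC loop	59		0	0	2	0.34	0.31	Yes
tRNA-Pro	16017A>G	35.0	Acceptor arm	7		1	0.33	1	0.17	0.63	Yes
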