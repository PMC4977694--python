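mirna_name	offset5	seed	MCF7	MDA-MB-231	T47D	BT20	BT474	MDA-MB-468	ZR-75	MCF10A
miR-10a-5p	0	ACCCTGT	81.9	4923.9	9254.5	7698.9	96.5	181.4	854.1	582.7
miR-10a-5p	+1	CCCTGTA	56.9	2158.4	3911.3	3660.0	64.2	65.0	477.0	273.0
miR-1307-3p	0	CTCGGCG	1159.2	737.2	2299.7	575.6	1894.2	554.8	2560.7	290.0
miR-1307-3p	+1	TCGGCGT	394.2	253.2	943.8	222.5	643.7	348.3	784.3	72.7
miR-140-3p	0	ACCACAG	180.9	486.8	117.4	289.0	149.1	63.0	181.2	199.2
miR-140-3p	+1	CCACAGG	407.7	851.6	284.8	568.7	217.6	95.2	306.2	332.8
miR-183-5p	0	ATGGCAC	1187.2	91.7	1065.9	1132.5	2017.2	1028.1	849.9	518.7
miR-183-5p	+1	TGGCACT	1102.0	44.0	831.3	822.5	1860.5	767.9	725.6	312.4
miR-203-3p	0	TGAAATG	2327.2	3.1	2514.6	544.1	5319.0	427.8	2870.3	71.3
miR-203-3p	+1	GAAATGT	2115.5	1.5	1137.8	329.8	2116.1	175.1	1104.8	23.1
miR-30a-3p	0	TTTCAGT	13.9	991.7	162.5	191.8	30.8	1033.2	108.8	239.7
miR-30a-3p	+1	TTCAGTC	3.7	305.1	53.5	65.8	6.6	311.7	35.8	44.1
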