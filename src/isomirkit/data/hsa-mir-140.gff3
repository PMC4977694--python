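##gff-version 3
# Mature miRNA coordinates on the hsa-mir-140 stem-loop (1-based, inclusive).
hsa-mir-140	isomirkit	miRNA	23	44	.	+	.	ID=hsa-miR-140-5p;Name=hsa-miR-140-5p;Derives_from=hsa-mir-140
hsa-mir-140	isomirkit	miRNA	62	82	.	+	.	ID=hsa-miR-140-3p;Name=hsa-miR-140-3p;Derives_from=hsa-mir-140
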