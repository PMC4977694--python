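mirna_name	mature_sequence
miR-10a-5p	TACCCTGTAGATCCGAATTTGTG
miR-1307-3p	ACTCGGCGTGGCGTCGGTCGTG
miR-140-3p	TACCACAGGGTAGAACCACGG
miR-183-5p	TATGGCACTGGTAGAATTCACT
miR-203-3p	GTGAAATGTTTAGGACCACTAG
miR-30a-3p	CTTTCAGTCGGATGTTTGCAGC
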