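name	fwd_name	fwd_seq	rev_name	rev_seq	gene
cox2	cox2-370F	CAAAGATGGATTCGACGGTTGG	cox2-776R	CCGGTATCAAACTCGCCCTT	cox2
cox3	cox3-467F	GGTTCAACGACACCCATTT	cox3-901R	TAGCGTGATGAGCCCATG	cox3
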