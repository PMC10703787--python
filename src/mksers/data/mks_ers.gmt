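MKS	12 mitotic kinases (mitosis, spindle checkpoint, G2-M transition); member syntax SYMBOL|probe_set	PLK1|202240_at	CDK1|203213_at	BUB1B|203755_at	NEK2|204641_at	TTK|204822_at	MELK|204825_at	PLK4|204887_s_at	CHEK1|205394_at	AURKA|208079_s_at	AURKB|209464_at	BUB1|209642_at	PBK|219148_at
ERS	4 genes of the Oncotype DX estrogen module	BCL2|203685_at	ESR1|205225_at	PGR|208305_at	SCUBE2|219197_s_at
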