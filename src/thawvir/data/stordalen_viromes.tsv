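sample	habitat	storage	replicate	total_reads	assembled_reads	viral_reads	votu_reads
palsa_chilled_A	palsa	chilled	A	10216080	540430	45972	26562
palsa_frozen_A	palsa	frozen	A	26000204	1279210	70200	59800
bog_frozen_A	bog	frozen	A	14499010	2611272	102944	44948
bog_frozen_B	bog	frozen	B	4446734	466018	53806	27126
bog_chilled_B	bog	chilled	B	15578086	4210756	1190166	532770
fen_chilled_A	fen	chilled	A	2108484	665226	242898	182174
fen_chilled_B	fen	chilled	B	2001976	649040	231428	168566
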