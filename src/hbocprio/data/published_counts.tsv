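variant	group	alt	total
SETBP1:c.4129G>C	NFE-TCGA	169	12388
SETBP1:c.4129G>C	NFE-ExAC-nonTCGA	593	54328
SETBP1:c.4129G>C	EUR-UKB-cancer	1792	107410
SETBP1:c.4129G>C	EUR-UKB-cancerfree	8652	513585
SETBP1:c.4129G>C	EUR-UKB-femaleBC	374	19799
SETBP1:c.4129G>C	EUR-UKB-female-cancerfree	4517	270628
C7orf34:c.248C>T	NFE-TCGA	44	12392
C7orf34:c.248C>T	NFE-ExAC-nonTCGA	132	54344
C7orf34:c.248C>T	EUR-UKB-cancer	389	108789
C7orf34:c.248C>T	EUR-UKB-cancerfree	1633	520670
C7orf34:c.248C>T	EUR-UKB-femaleBC	63	20110
C7orf34:c.248C>T	EUR-UKB-female-cancerfree	850	274273
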