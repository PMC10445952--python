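gene	region_start	region_end	fwd	rev	tm_fwd	tm_rev	expected_size
D-loop	270	336	GAATGGTTACCGGACATAAAC	CCATTCATAGTTAGGTGACTT	50	49	67
ND4	11366	11530	CCTTGTACCTATTCTAATACTG	CATACTCTTGCCCACAGCC	47.5	55.9	165
D-loop	216	436	CTCATTTACCCTCCCCATAA	GTTGCTGATCTCTCGTGAG	50	51	221
COX1	8050	8341	TATTCATCGTCTGAGAAGCCT	TGGTTGGCCATGTGAGATG	53.1	55.3	292
ND2	6008	6177	ATTAACCGGCTTCATGCCAG	TTATGTGGTTTGATGAGTTGG	55.7	50.7	170
rRNA	1996	2157	AGGTCAAGGTATAGCCTATGA	GTATGTACGTGCCTCAGAG	50	51	162
ND2	5529	5853	ATATTAACAATAGCAATCGCAAC	AGGTGAGAATAGTGAGTTGTG	49.7	51.8	325
ND4	12476	12796	AACACAAACTACGAACGGAT	TATGAGAAGATGTTCTCGAG	48	48	321
rRNA	3916	4253	TCAACTGCCAAGAACCCCC	GATTGGCTCTTTAATGAATAGT	57.8	48.3	338
CYTB	15115	15391	CAATACGGCTGACTCATCCA	CTCAGGCTCACTCTACTAG	52	51	277
D-loop	1150	1623	CACTTAACTCCCCTCACAAG	TAGCTGGTGCAGATAACATG	52	50	474
ND5	14683	15016	CCTCAATCCTCCTACATACT	ACAGACTGCTAATAGGGAGC	50.4	53.8	333
CYTB	14996	15477	GCTCCCTATTAGCAGTCTGT	GATAGTAATACCTGCGATTGC	52	50	482
D-loop	369	470	ACCCATTTGGTTATGCTCGC	TGAGACTGGTCATGAAGTAC	52	50	101
tRNA	6512	6625	CCCGGCACACTTTAGTGTG	TGAAGCGTTAGGCTGTAGTC	53	52	114
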