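name	start	end	size	start_codon	stop_codon	anticodon	strand	space
D-loop	1	1227	1227					
rRNA-small	1297	2272	976				H	70
rRNA-large	2346	3966	1621				H	74
ND1	4050	5024	975	ATG	TAA		H	84
ND2	5241	6281	1041	ATG	TAG		H	217
tRNA-Cys	6508	6573	66			GCA	L	227
COX1	6645	8132	1488	ATG	T--		H	72
tRNA-Ser	8124	8258	135			UGA/GCU	L	-8
tRNA-Asp	8261	8329	69			GUC	L	3
COX2	8331	9014	684	ATG	TAA		H	2
ATP6	9240	9923	884				H	226
COX3	9923	10706	784	ATG	T--		H	-1
ND3	10776	11126	351	ATG	TAA		H	70
ND4L	11196	11492	297	ATG	TAA		H	70
ND4	11486	12863	1378	ATG	T--		H	-6
ND5	13071	14888	1818	ATG	TAA		H	208
CYTB	14893	16035	1143	ATG	TAA		H	5
tRNA-Pro	16108	16177	70			UGG	L	73
ND6	16184	16705	522	ATG	TAA		L	7
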