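protein_id	start	end	name	disorder_flag	functional_unit
APC	1284	1537	APC_1284-1537	1
ASXL1	1102	1107	ASXL1_1102-1107	1
BCL2	2	80	BCL2_2-80	1
CALR	358	384	CALR_358-384	1
CARD11	111	134	CARD11_111-134	1
CARD11	207	266	CARD11_207-266	1
CARD11	337	436	CARD11_337-436	1
CBL	365	374	CBL_365-374	1
CCND3	278	290	CCND3_278-290	1
CD79B	191	199	CD79B_191-199	1
CEBPA	293	327	CEBPA_293-327	1	motif:293-327
CSF1R	969	969	CSF1R_969	1
CTNNB1	32	45	CTNNB1_32-45	1	motif:32-45
EIF1AX	4	15	EIF1AX_4-15	1
EPAS1	529	539	EPAS1_529-539	1
ESR1	303	303	ESR1_303	1
FOXA1	248	268	FOXA1_248-268	1
FOXL2	134	134	FOXL2_134	1
FOXO1	19	26	FOXO1_19-26	1
HIST1H3B	28	28	HIST1H3B_28	1
ID3	48	70	ID3_48-70	1
MED12	44	44	MED12_44	1
MLH1	379	385	MLH1_379-385	1	linker:379-385
MYC	57	60	MYC_57-60	1
MYCN	44	44	MYCN_44	1
MYOD1	122	122	MYOD1_122	1
NFE2L2	20	38	NFE2L2_20-38	1	motif:20-38
NFE2L2	75	82	NFE2L2_75-82	1	motif:75-82
PAX5	75	80	PAX5_75-80	1
RPS15	129	145	RPS15_129-145	1
SETBP1	858	880	SETBP1_858-880	1
SMARCB1	368	381	SMARCB1_368-381	1
SRSF2	95	95	SRSF2_95	1
USP8	713	736	USP8_713-736	1
VHL	54	136	VHL_54-136	1
VHL	144	193	VHL_144-193	1
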