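# Protein-change notation for the grain-number candidate genes differing
# between the parents Luohui 9 (indica) and RPY geng (japonica), with the
# published deleteriousness call (1 = predicted deleterious by PROVEAN).
# PROVEAN scores themselves were not published; the call column carries the
# published annotation.
gene	notation	deleterious	provean_score
Gn1a	N535K
Gn1a	H116R
Gn1a	G54A
Gn1a	A79_A80del
NOG1	E346del	1
PYL1	F49C
LAX1	D74E	1
LAX1	S117A
LP	L3fs	1
LP	S32fs	1
PYL4	A86P
OSH1	Q23_H24dup
DST	T201dup
DST	A124_V125insAAAAAV
GNP1	V41A
An-1	Q87fs	1
LAX2	H65_H66dup
LAX2	T131_P138del
LAX2	L177P
LAX2	A180T
LAX2	P210A
LAX2	R225M	1
LAX2	A237del
LAX2	A237V
APO1	G292_G294del
APO1	R204G
APO1	I17V
DTH7	D68E
DTH8	N295S
PAY1	W2R
PAY1	P150T
GAD1	R101fs	1
IPA1	L292I
DEP1	L228H
DEP1	Q283fs	1
DEP1	C324S
TAW1	A33_A34insSASA
SP1	A550_G551del
SP1	D475_G476del	1
SP1	A401G
SP1	V328A
SP1	H301_A306del
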