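gene	transcript	exons
ASXL1	NM_015338	12
BRAF	NM_004333	15
CALR	NM_004343	9
CSF3R	NM_000760	14,17
DNMT3A	NM_022552	23
FLT3	NM_004119	13–15,20
IDH1	NM_005896	4
IDH2	NM_002168	4
JAK2	NM_004972	14
KIT	NM_000222	8,17
KRAS	NM_033360	2,3
MPL	NM_005373	10
MYD88	NM_002468	5
NPM1	NM_002520	11
NRAS	NM_002524	2,3
RUNX1	NM_001754	4–9,
SETBP1	NM_015559	4
SF3B1	NM_012433	14–16
SRSF2	NM_003016	1
TP53	NM_000546	2–12
U2AF1	NM_006758	2,6
WT1	NM_024424	5–10
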