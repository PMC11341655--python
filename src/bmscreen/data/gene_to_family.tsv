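gene	families
JAK1	JAK
JAK2	JAK
JAK3	JAK
ERBB2	HER2
FGFR1	FGFR
FGFR2	FGFR
FGFR3	FGFR
FGFR4	FGFR
STK11	ERK
TP53	HDAC;HSP90
ATM	MEK
KIT	KIT
MAP2K1	MEK
PIK3CA	PI3K
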