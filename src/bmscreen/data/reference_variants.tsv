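sample_id	source	gene	c_hgvs	p_hgvs	af_percent
BM28	TISSUE	STK11	c.289_290+2delAAGT		59.6
BM28	TISSUE	TP53	c.734G>T	p.G245V	69.8
BM28	CULTURE	STK11	c.289_290+2delAAGT		90.5
BM28	CULTURE	TP53	c.734G>T	p.G245V	92.5
BM31	TISSUE	KIT	c.2447A>T	p.D816V	29.5
BM31	TISSUE	JAK3	c.2164G>A	p.V722I	50.1
BM31	CULTURE	KIT	c.2447A>T	p.D816V	31.7
BM31	CULTURE	JAK3	c.2164G>A	p.V722I	51.0
BM32	TISSUE	ATM	c.2572T>C	p.F858L	40.8
BM32	CULTURE	ATM	c.2572T>C	p.F858L	44.3
BM35	TISSUE	FGFR3	c.1345C>T	p.P449S	49.1
BM35	TISSUE	KRAS	c.34G>T	p.G12C	50.9
BM35	CULTURE	FGFR3	c.1345C>T	p.P449S	52.6
BM35	CULTURE	KRAS	c.34G>T	p.G12C	62.8
BM36	TISSUE	JAK3	c.2152G>C	p.V718L	31.6
BM36	CULTURE	JAK3	c.2152G>C	p.V718L	47.5
BM36-2	TISSUE	JAK3	c.2152G>C	p.V718L	36.5
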