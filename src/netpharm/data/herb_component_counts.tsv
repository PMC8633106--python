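herb	code	n_components	n_active
Bupleurum scorzonerifolium Willd.	CH	354	79
Citrus reticulata Blanco	CP	74	14
Ligusticum striatum DC.	CX	193	35
Cyperus rotundus L.	XF	104	29
Citrus x aurantium L.	ZQ	17	6
Paeonia lactiflora Pall.	SY	166	45
Glycyrrhiza uralensis Fisch. ex DC.	GC	283	82
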