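gene	position	posterior	branch
CALR	83	0.971	Vertebrates
CALR	155	0.971	Vertebrates
CALR	177	0.990	Vertebrates
CALR	267	0.995	Vertebrates
CALR	307	0.994	Vertebrates
CALR	336	0.991	Vertebrates
CALR	360	0.999	Vertebrates
CTNNB1	121	0.999	Vertebrates
CTNNB1	206	0.993	Vertebrates
CTNNB1	250	0.998	Vertebrates
CTNNB1	287	0.991	Vertebrates
CTNNB1	411	0.998	Vertebrates
CTNNB1	433	0.993	Vertebrates
CTNNB1	525	0.997	Vertebrates
CTNNB1	552	0.998	Vertebrates
CTNNB1	556	0.916	Vertebrates
VHL	127	0.957	Vertebrates
VHL	132	0.942	Vertebrates
VHL	141	0.923	Vertebrates
VHL	171	0.947	Vertebrates
VHL	183	0.963	Vertebrates
VHL	185	0.920	Vertebrates
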