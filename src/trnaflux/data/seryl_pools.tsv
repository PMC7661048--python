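strain	group	p_UGA	p_CGA
SBW25	wild_type	0.0059	0.015
W1-L	wild_type	0.0056	0.014
dserCGA-1	deletion	0.0050	0
dserCGA-2	deletion	0.0047	0
M1-L	duplication	0.013	0
M2-Lop	duplication	0.012	0
M2-L	duplication	0.012	0
M3-L	duplication	0.011	0
M4-L	duplication	0.010	0
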