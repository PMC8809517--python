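fifth	last	A	C	G	U
N	D	0	0	0	1
N	S	0	1	0	0
T	D	0	0	1	0
T	N	1	0	0	0
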