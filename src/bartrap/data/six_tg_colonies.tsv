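gene	colonies	insertion_sites
Msh6	33	14
Msh2	8	4
Mlh1	1	1
Pms2	1	1
Csmd1	2	1
Eif1a	2	1
none	2	2
other	29	1
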