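table	bin_code	bin_name	total	acidic	alkaline
1	34.1	transport.p- and v-ATPases	711	415	296
1	34.1.1	transport.p- & v-ATPases.H+-transporting two-sector ATPase	1469	821	648
1	34.2	transport.porins	346	224	122
1	34.2	transport.sugars	157	77	80
1	34.3	transport.H+ transporting pyrophosphatase	573	315	258
1	34.5	transport.ammonium	177	95	82
1	34.6	transport.sulphate	9	8	1
1	34.8	transport.metabolite transporters at the envelope membrane	67	37	30
1	34.9	transport.metabolite transporters at the mito membrane	434	250	184
1	34.12	transport.metal	29	19	10
1	34.14	transport.unspecified cations	399	263	136
1	34.15	transport.potassium	53	27	26
1	34.16	transport.ABC transporters & multidrug resistance systems	425	253	172
1	34.18	transport.unspecified anions	124	85	39
1	34.19	transport.Major Intrinsic Proteins	222	116	106
1	34.21	transport.calcium	195	93	102
1	34.99	transport.Misc	163	96	67
2	31.4	cell.vesicle transport	1618	1002	616
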