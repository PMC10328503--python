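promoter	size_bp	in_array	integrated
aha-1	330	Y	Y
hlh-16	514	Y	N
ceh-40	965	Y	Y
ceh-10	1172	Y	Y
ahr-1	1387	Y	N
mdl-1	2000	Y	Y
egl-43	2001	Y	N
ceh-20	2015	Y	Y
ceh-43	2096	Y	Y
daf-7	2524	Y	Y
lin-11	2857	Y	Y
egl-46	4477	N	N
nhr-67	5545	Y	Y
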