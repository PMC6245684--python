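RF1	RF2	target	label	condition
0	0	0	shift galactose-to-glucose (time series)	glucose
0	1	0	over-expression of GAL80	glucose
1	0	1	over-expression of GAL4 while GAL80 inactive	glucose
1	1	0	no direct perturbation; PPI Gal4-Gal80 in glucose turns off SWI5	glucose
0	0	0	no direct perturbation; adopted from glucose	galactose
0	1	0	over-expression of GAL80 represses GAL4	galactose
1	0	1	over-expression of GAL4 while GAL80 inactive	galactose
1	1	1	shift glucose-to-galactose (time series)	galactose
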