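tool	threshold_label	n_missing	sensitivity	specificity	accuracy	ppv	npv
HSF	0.2	28	0.8941	0.3958	0.5808	0.4663	0.8636
SpliceAI	0.2	11	0.8987	0.9162	0.9106	0.8353	0.9503
SSF	5%	5	0.7317	0.9294	0.8651	0.8333	0.8778
MES	10%	1	0.7381	0.9070	0.8516	0.7949	0.8764
NNSplice	5%	11	0.6923	0.8631	0.8089	0.7013	0.8580
Alamut23	2/3	14	0.7237	0.9162	0.8560	0.7971	0.8793
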