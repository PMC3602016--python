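source	target	f_score
dACC	rACC	51.61
dACC	Parahippocampus	12.65
SMA	Precuneus	14.23
SMA	Insula	4.73
rACC	SMA	8.79
rACC	dlPFC	7.96
rACC	Precuneus	11.61
rACC	Parahippocampus	3.45
rACC	Insula	13.98
rACC	vmPFC	33.10
dlPFC	rACC	8.44
Precuneus	dlPFC	4.29
Precuneus	Parahippocampus	15.13
Precuneus	vmPFC	4.78
Parahippocampus	dACC	34.03
Parahippocampus	rACC	11.10
Parahippocampus	Insula	30.47
Parahippocampus	vmPFC	3.25
Insula	dACC	15.01
Insula	SMA	31.32
Insula	Parahippocampus	75.31
Insula	vmPFC	23.08
vmPFC	dACC	18.12
vmPFC	Precuneus	42.16
vmPFC	Parahippocampus	6.80
vmPFC	Insula	8.92
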