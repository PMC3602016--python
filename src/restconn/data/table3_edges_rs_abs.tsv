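source	target	f_score
dACC	SMA	3.61
dACC	Precuneus	18.07
dACC	Parahippocampus	7.18
dACC	Insula	63.39
dACC	vmPFC	36.24
rACC	SMA	4.99
rACC	Insula	19.64
rACC	vmPFC	13.23
dlPFC	Insula	7.59
Precuneus	dACC	25.31
Precuneus	dlPFC	7.30
Precuneus	Insula	108.81
Precuneus	vmPFC	15.90
Parahippocampus	dACC	4.71
Parahippocampus	Insula	15.00
Insula	dACC	47.97
Insula	SMA	43.31
Insula	rACC	44.46
Insula	dlPFC	22.61
Insula	Precuneus	70.57
Insula	Parahippocampus	24.92
Insula	vmPFC	62.23
vmPFC	dlPFC	19.66
vmPFC	Precuneus	9.57
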