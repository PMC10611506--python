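name	locus_group	constituents
syn144K	ABC	144:K
syn116F	ABC	116:F
syn17R	ABC	17:R
syn6R	DRB	6:R
dec60R	ABC	60:R
dec228V	ABC	228:V
dec340K	ABC	340:K
dec52P	DQ	52:P
dec96E	DP	96:E,84:D
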