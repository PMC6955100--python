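# 6-month cohort: longer dendrites (the planted contrast)
label = AD06
region = PFC
n_neurons = 60
length_multiplier = 1.2
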