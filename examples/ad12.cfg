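# 12-month cohort: baseline growth parameters
label = AD12
region = PFC
n_neurons = 60
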