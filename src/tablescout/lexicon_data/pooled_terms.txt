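all patients
all participants
total
overall
whole cohort
study population
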