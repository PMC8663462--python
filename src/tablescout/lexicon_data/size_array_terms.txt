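n
no. of patients
no. of participants
number of patients
number of participants
patients, n
participants, n
sample size
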