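male
female
men
women
site a
site b
site c
centre a
centre b
age <65
age >=65
age 65 and over
under 65
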