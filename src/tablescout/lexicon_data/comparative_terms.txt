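p value
p-value
mean difference
difference
difference (95% ci)
95% ci
odds ratio
risk ratio
relative risk
hazard ratio
effect size
or (95% ci)
rr (95% ci)
hr (95% ci)
mean difference (95% ci)
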