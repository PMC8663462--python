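placebo
high-flow nasal cannula
continuous positive airway pressure
cognitive behavioural therapy
oseltamivir
dexamethasone
metformin
atorvastatin
intravenous iron
mindfulness training
aerobic exercise
acupuncture
vitamin d supplementation
nurse-led telephone coaching
epidural analgesia
ketamine infusion
probiotic supplementation
pulmonary rehabilitation
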