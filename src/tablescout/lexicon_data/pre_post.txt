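pre
post
before
after
baseline
follow-up
followup
follow up
final
discharge
admission
endpoint
end of treatment
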