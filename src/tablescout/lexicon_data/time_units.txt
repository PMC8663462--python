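minute
minutes
min
hour
hours
h
hr
hrs
day
days
d
week
weeks
wk
wks
month
months
mo
mos
year
years
y
yr
yrs
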