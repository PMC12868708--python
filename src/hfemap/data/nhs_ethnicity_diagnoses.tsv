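stratum	count	denominator
White Irish	1355	225320
White British	53575	32380055
Chinese	310	241320
White - Any other White background	2470	3279680
Black or Black British - Caribbean	325	437095
Black or Black British - African	675	1047810
Any Other Ethnic Group	925	1440830
Black or Black British - Any other Black background	255	399380
Asian or Asian British - Pakistani	590	1270035
Asian or Asian British - Any other Asian background	430	933260
Asian or Asian British - Bangladeshi	180	450140
Asian or Asian British - Indian	490	1319040
Mixed - All Mixed backgrounds	365	1070945
All	70365	63664825
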