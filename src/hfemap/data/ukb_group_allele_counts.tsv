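group	n	mac_c282y	mac_h63d
Genomically British	408780	63763	123466
German	2088	254	617
French	801	80	285
Polish	612	42	182
Italian	808	31	230
Ashkenazi Jewish	2868	71	724
Afro-Caribbean	2171	34	70
Sri Lankan	654	3	133
British Indian	5317	23	834
British Pakistani	1645	4	239
Kenyan	1049	2	170
East Asian	2244	2	134
West African	1317	0	15
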