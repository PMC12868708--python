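stratum	count	denominator
Cheshire & Merseyside	6635	1924680
Manchester	3700	1730190
London	4270	2184795
Lancashire & S Cumbria	2190	1167890
Yorkshire	5970	3569205
W-Midlands	3665	2259905
North	3645	2277515
Cornwall	760	478210
E-Midlands	4715	3009140
East	5300	3993515
Southwest	4530	3459385
Southeast	6720	5176910
Birmingham	1455	1144980
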