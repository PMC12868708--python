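region	prevalence_pct	risk_pct
Cheshire & Merseyside	0.345	0.542
London	0.195	0.376
E-Midlands	0.157	0.388
Manchester	0.214	0.532
W-Midlands	0.162	0.421
Southwest	0.131	0.356
East	0.133	0.364
Cornwall	0.159	0.441
Yorkshire	0.167	0.467
Lancashire & S Cumbria	0.188	0.525
Southeast	0.130	0.366
North	0.160	0.519
Birmingham	0.127	0.427
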