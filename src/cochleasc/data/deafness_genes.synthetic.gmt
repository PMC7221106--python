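hereditary_synthetic	synthetic example deafness gene set	Myo7a	Myo6	Cdh23	Pcdh15	Tmc1	Slc26a4	Gjb2	Otof
gwas_synthetic	synthetic example acquired hearing-loss set	Eya4	Grhl2	Triobp	Ildr1	Mettl13
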