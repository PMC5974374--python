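E2F24_UP	24-gene E2F signature, 11 transcripts overexpressed in E2F-high tumors	BIRC5	LMNB1	POLA2	DEPDC1	MCM2	CDK1	PTTG1	CDC20	PLK1	KPNA2	AURKA
E2F24_DN	24-gene E2F signature, 13 transcripts downregulated in E2F-high tumors	RHBDL2	DLEU7-AS1	TMEM63A	IGSF9	NEIL1	BDKRB2	PDZK1IP1	ERN2	CTSE	VSIG2	BCL2L15	LOC100505633	TXNIP
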