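# Published key-protein table for the three thalamo-amygdala synaptic-activity
# networks (normal hearing NH, acoustic stimulation AS, tinnitus Tin).
# Per condition: the top-3 high-degree proteins (hub, degree) and their
# high-score interaction partners (partner, combined score) above the
# network-wide 90th-percentile combined-score threshold.
# A hub row with an empty partner column has no qualifying partner.
condition	cs_threshold	hub	hub_degree	partner	combined_score
NH	930	BDNF	18	NTRK2	999
NH	930	BDNF	18	NTF3	991
NH	930	BDNF	18	GDNF	963
NH	930	CASP3	14	MAPK8	943
NH	930	PVALB	11
AS	896	BDNF	54	NTRK2	999
AS	896	BDNF	54	MECP2	965
AS	896	BDNF	54	CREB1	956
AS	896	BDNF	54	SLC6A4	922
AS	896	PVALB	45	CALB1	964
AS	896	DLG4	42	SYP	998
AS	896	DLG4	42	GRIN1	998
AS	896	DLG4	42	NOS1	996
AS	896	DLG4	42	SYNGAP1	996
AS	896	DLG4	42	SHANK1	992
AS	896	DLG4	42	FMR1	938
AS	896	DLG4	42	HTR2A	915
AS	896	DLG4	42	GRM5	902
Tin	908	BDNF	67	NGFR	999
Tin	908	BDNF	67	NTRK1	999
Tin	908	BDNF	67	NTRK3	999
Tin	908	BDNF	67	CREB1	956
Tin	908	BDNF	67	NTF3	991
Tin	908	BDNF	67	GDNF	963
Tin	908	APP	60	ApoE	999
Tin	908	APP	60	PSEN1	999
Tin	908	APP	60	PRNP	998
Tin	908	APP	60	CLU	998
Tin	908	APP	60	MAPT	995
Tin	908	APP	60	SNCA	993
Tin	908	APP	60	NGFR	959
Tin	908	APP	60	ACHE	937
Tin	908	APP	60	SYP	918
Tin	908	APP	60	CASP3	908
Tin	908	TNF	52	JUN	989
Tin	908	TNF	52	FASLG	984
Tin	908	TNF	52	CASP3	939
Tin	908	TNF	52	PTGS2	916
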