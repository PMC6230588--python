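gene	functionality	cdna_accession	identity_pct
TRBV1	F	AY690918	99.7
TRBV2-1	P		
TRBV2-2	P		
TRBV2-3	P		
TRBV2-4	F	AY691163	97.1
TRBV2-5	P		
TRBV3	F	AY691035	97.9
TRBV4-1	F	AY691152	99.7
TRBV4-2	P		
TRBV4-3/4	F	AY691156	100
TRBV4-5	F	AY691000	99.4
TRBV5-1	F	AY691018	99.7
TRBV5-2	P	AY691147	97.7
TRBV5-3	F		
TRBV6	P	AY690936	99.1
TRBV7-1	F	AY691001	100
TRBV7-2	F	AY691161	100
TRBV8	P		
TRBV10	F	AY690909	100
TRBV11	F	AY690947	99.1
TRBV12-1	F	AY691138	99.7
TRBV12-2	P	AY690854	99.7
TRBV14	F		
TRBV15	F	AY691160	100
TRBV19	F	AY691020	99.4
TRBV20-1	F	AY690891	100
TRBV20-2	F	AY690903	100
TRBV20-3	F	AY690934	98.5
TRBV21	F	AY690915	100
TRBV22	P		
TRBV23	P		
TRBV24	F	AB079527	100
TRBV25	F	AY690938	99.4
TRBV27	F	AY690919	98.8
TRBV28	P		
TRBV29	F	AY691002	100
TRBV30	F	AY690884	100
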