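v_gene	TRBJ1-1	TRBJ1-2	TRBJ1-3	TRBJ1-7	TRBJ3-3	TRBJ3-4	TRBJ3-5	TRBJ2-1	TRBJ2-2	TRBJ2-3	TRBJ2-4	TRBJ2-6	total
TRBV1	0	0	0	0	0	1	0	0	0	0	0	0	1
TRBV4-1	0	1	0	1	0	0	1	0	0	1	0	0	4
TRBV4-3/4	1	2	0	0	0	0	0	0	0	0	0	0	3
TRBV4-5	0	0	0	1	0	0	0	0	0	0	0	0	1
TRBV4S7	0	0	1	0	0	0	0	1	0	0	0	0	2
TRBV5-1	0	0	0	0	1	0	0	0	1	0	0	0	2
TRBV6	0	1	0	0	0	0	0	0	0	0	0	0	1
TRBV7-1	0	2	0	1	0	0	1	0	0	0	1	0	5
TRBV7-2	0	1	0	0	0	0	0	0	0	0	0	0	1
TRBV11	1	0	0	0	0	0	0	0	0	0	0	0	1
TRBV20-1	0	0	0	0	0	0	0	0	0	0	1	0	1
TRBV20-3	2	0	0	1	0	0	0	0	0	0	0	1	4
TRBV12-1	0	0	0	0	1	0	0	1	1	0	0	0	3
TRBV21	0	0	0	0	0	0	1	0	0	0	0	0	1
TRBV25	0	0	1	0	0	0	1	0	1	0	0	0	3
TRBV27	0	0	0	0	0	0	1	0	0	0	0	0	1
Total	4	7	2	4	2	1	5	2	3	1	2	1	34
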