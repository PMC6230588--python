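v_gene	TRBJ1-1	TRBJ1-2	TRBJ1-3	TRBJ1-5	TRBJ1-6	TRBJ1-7	TRBJ3-1	TRBJ3-2	TRBJ3-3	TRBJ3-4	TRBJ3-5	TRBJ3-7	TRBJ2-1	TRBJ2-2	TRBJ2-3	TRBJ2-4	TRBJ2-5	TRBJ2-6	nd	total
TRBV2-4	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	1	0	2
TRBV3	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1
TRBV4-1	0	1	0	0	0	1	0	1	0	0	1	0	0	0	0	0	0	3	0	7
TRBV4-3/4	1	3	1	3	0	0	1	0	2	1	0	0	0	1	0	1	0	1	0	15
TRBV4-5	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	1
TRBV4S6	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1
TRBV4S7	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1
TRBV5-1	0	4	0	2	1	3	1	0	0	1	1	1	1	1	1	1	2	2	1	23
TRBV5-2	1	0	0	0	1	0	2	1	0	0	1	0	1	1	1	1	0	1	1	12
TRBV5S4	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1
TRBV7-1	2	2	3	1	1	1	1	1	1	2	2	0	0	0	1	1	2	4	0	25
TRBV7-2	0	0	0	1	0	0	0	0	2	0	0	0	1	0	1	0	1	2	0	8
TRBV7S3	0	5	1	0	0	1	0	1	0	0	0	0	0	1	1	0	1	1	0	12
TRBV7S4	1	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2
TRBV12-1	2	5	3	1	0	0	1	2	1	2	5	0	0	0	4	0	3	7	1	37
TRBV15	1	1	0	0	0	0	0	0	1	0	0	0	0	0	0	1	0	1	0	5
TRBV19	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	1
TRBV21	1	3	1	1	0	1	0	0	0	0	0	0	1	0	0	0	0	0	0	8
TRBV29	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	1
Total	10	27	10	9	3	7	6	6	8	7	11	1	4	4	9	5	9	24	3	163
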