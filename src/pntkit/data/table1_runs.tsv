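# Per-run handedness statistics fixture, version 1.
# 32 independent assembly runs per monomer type.  left/right are the
# fractional expert-style scores (blank cells transcribed as 0); value is
# the per-run signed chirality index (positive = right-handed).
run	monomer	left	right	value
1	L	0	1	-0.006
2	L	0	1	0.033
3	L	0	1	0.009
4	L	0	1	0.043
5	L	0	1	0.005
6	L	0.5	0.5	-0.032
7	L	0	1	0.018
8	L	1	0	-0.027
9	L	1	0	-0.038
10	L	0.5	0.5	0.042
11	L	1	0	0.008
12	L	0	1	0.016
13	L	0.5	0.5	0.062
14	L	0	1	0.001
15	L	0	1	0.039
16	L	0	1	0.031
17	L	0.5	0.5	0.040
18	L	0	1	0.003
19	L	0	1	-0.004
20	L	0.5	0.5	0.015
21	L	0	1	0.073
22	L	0	1	0.050
23	L	0	1	0.059
24	L	0	1	0.054
25	L	0	1	0.048
26	L	0	1	0.015
27	L	0.5	0.5	0.044
28	L	0.5	0.5	0.086
29	L	0.5	0.5	0.003
30	L	0	1	-0.021
31	L	0	1	0.043
32	L	0	1	0.034
1	D	0.8	0.2	-0.046
2	D	1	0	-0.098
3	D	0.2	0.8	-0.031
4	D	0.8	0.2	-0.045
5	D	1	0	-0.001
6	D	0.5	0.5	-0.007
7	D	1	0	-0.030
8	D	0	1	-0.031
9	D	1	0	-0.023
10	D	1	0	-0.002
11	D	0.5	0.5	0.050
12	D	1	0	-0.027
13	D	0.5	0.5	0.004
14	D	0.5	0.5	0.003
15	D	0.5	0.5	0.018
16	D	1	0	-0.003
17	D	1	0	0.004
18	D	0.5	0.5	-0.028
19	D	1	0	-0.043
20	D	0.8	0.2	-0.063
21	D	0.5	0.5	0.003
22	D	0.2	0.8	-0.054
23	D	0.5	0.5	-0.030
24	D	0.5	0.5	-0.029
25	D	1	0	-0.022
26	D	1	0	-0.011
27	D	0.5	0.5	-0.039
28	D	0.5	0.5	0.012
29	D	0.8	0.2	-0.012
30	D	0.5	0.5	-0.011
31	D	0.5	0.5	-0.007
32	D	0.8	0.2	-0.016
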