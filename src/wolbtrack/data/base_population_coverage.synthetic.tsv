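sample_id	mean_depth_nuclear	mean_depth_wolbachia	mean_depth_mtdna	wolbachia_breadth
w2	17.07	209.91	1850.0	0.993
w4	24.76	3.44	2400.0	0.104
w5	24.01	2.88	2100.0	0.093
w6	16.69	139.10	1600.0	0.990
w7	20.90	2.71	1900.0	0.088
w12	24.94	3.23	2750.0	0.101
w13	33.20	3.75	3600.0	0.112
w14	39.89	272.23	6400.0	0.996
w15	25.66	2.67	2650.0	0.085
w16	22.56	2.727	2300.0	0.097
w18	21.57	138.56	2650.0	0.988
w19	32.57	3.23	3500.0	0.106
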