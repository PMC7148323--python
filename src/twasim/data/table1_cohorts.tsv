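cohort	sex	n	p_under	p_normal	p_over	p_obese
NHANES	women	679	0.019	0.303	0.267	0.411
NHANES	men	668	0.012	0.254	0.356	0.377
GTEx	women	116	0.000	0.353	0.440	0.207
GTEx	men	211	0.000	0.280	0.445	0.275
CRIC	women	588	0.015	0.252	0.223	0.510
CRIC	men	841	0.001	0.141	0.360	0.497
GENE	women	91	0.011	0.725	0.264	0.000
GENE	men	102	0.000	0.676	0.314	0.010
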