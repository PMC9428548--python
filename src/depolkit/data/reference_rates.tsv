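condition	rate	sd	n	units
depol/MCAK	2.12	0.17	18	um/min
depol/MCAK-EGFP	1.38	0.15	6	um/min
depol/Con13	0.67	0.28	13	um/min
depol/Anc13	23.05	5.23	12	um/min
depol/MCAK-M	2.11	0.87	18	um/min
depol/MCAK+taxol	0.02	0.01	6	um/min
depol/Anc13+taxol	1.01	0.59	12	um/min
depol/Anc13+ADP	0.04	0.01	6	um/min
depol/basal	0.02	0.01	12	um/min
depol/MCAK-Anc13	19.50	4.87	1	um/min
kon/Anc13	62.4	21.5	1	nM^-1 s^-1 um^-1
kon/MCAK	0.52	0.34	1	nM^-1 s^-1 um^-1
koff_lattice/Anc13	1.36	0.06	1	s^-1
koff_end/Anc13	1.23	0.10	1	s^-1
koff_lattice/MCAK	2.90	0.16	1	s^-1
koff_end/MCAK	0.98	0.06	1	s^-1
atpase_basal/Anc13	0.44	0.04	3	s^-1
atpase_tubulin/Anc13	3.76	0.81	8	s^-1
atpase_mt/Anc13	8.07	0.63	3	s^-1
atpase_basal/MCAK	0.002	0.001	4	s^-1
atpase_tubulin/MCAK	0.25	0.10	7	s^-1
atpase_mt/MCAK	3.69	0.38	4	s^-1
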