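# Curated dinucleotide physicochemical property table, v1.
# 16 standard dinucleotides x 15 properties (6 conformational, 9 thermodynamic/
# mechanical), assembled from published B-DNA dinucleotide parameter sets
# (crystallographic step geometry; unified nearest-neighbor thermodynamics;
# stacking, melting and deformability scales). Values are raw; the loader
# min-max normalizes each property to [0,1] over the 16 pairs.
dinucleotide	twist	tilt	roll	shift	slide	rise	stacking_energy	enthalpy	entropy	free_energy	melting_tm	propeller_twist	deformability	bendability	duplex_disrupt_energy
AA	35.1	-1.4	0.7	-0.03	-0.08	3.27	-5.37	-7.9	-22.2	-1.00	54.50	-17.3	2.9	-0.280	1.9
AC	31.5	-0.1	0.7	0.13	-0.58	3.36	-10.51	-8.4	-22.4	-1.44	97.73	-6.7	2.3	-0.006	1.3
AG	31.9	-1.7	4.5	0.09	-0.25	3.34	-6.78	-7.8	-21.0	-1.28	58.42	-14.3	2.1	0.017	1.6
AT	29.3	0.0	1.1	0.00	-0.59	3.31	-6.57	-7.2	-20.4	-0.88	57.02	-16.9	1.6	-0.183	1.5
CA	37.3	0.5	4.7	0.09	0.53	3.33	-6.57	-8.5	-22.7	-1.45	54.71	-8.6	9.8	0.134	1.9
CC	32.9	0.1	3.6	0.05	-0.22	3.42	-8.26	-8.0	-19.9	-1.84	85.97	-12.8	6.1	-0.032	3.1
CG	36.1	0.0	5.4	0.00	0.41	3.39	-9.69	-10.6	-27.2	-2.17	72.55	-11.2	12.1	0.180	3.6
CT	31.9	1.7	4.5	-0.09	-0.25	3.34	-6.78	-7.8	-21.0	-1.28	58.42	-14.3	2.1	0.017	1.6
GA	36.3	-1.5	1.9	-0.13	0.09	3.37	-9.81	-8.2	-22.2	-1.30	86.44	-13.7	4.5	0.015	1.6
GC	33.6	0.0	0.3	0.00	-0.38	3.40	-14.59	-9.8	-24.4	-2.24	136.12	-11.1	4.0	-0.077	3.1
GG	32.9	-0.1	3.6	-0.05	-0.22	3.42	-8.26	-8.0	-19.9	-1.84	85.97	-12.8	6.1	-0.032	3.1
GT	31.5	0.1	0.7	-0.13	-0.58	3.36	-10.51	-8.4	-22.4	-1.44	97.73	-6.7	2.3	-0.006	1.3
TA	37.8	0.0	3.3	0.00	0.05	3.42	-3.82	-7.2	-21.3	-0.58	36.73	-11.1	6.3	0.025	0.9
TC	36.3	1.5	1.9	0.13	0.09	3.37	-9.81	-8.2	-22.2	-1.30	86.44	-13.7	4.5	0.015	1.6
TG	37.3	-0.5	4.7	-0.09	0.53	3.33	-6.57	-8.5	-22.7	-1.45	54.71	-8.6	9.8	0.134	1.9
TT	35.1	1.4	0.7	0.03	-0.08	3.27	-5.37	-7.9	-22.2	-1.00	54.50	-17.3	2.9	-0.280	1.9
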