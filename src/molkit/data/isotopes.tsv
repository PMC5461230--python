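# Monoisotopic masses and natural abundances (CODATA/IUPAC snapshot,
# masses to six decimals).
# Columns: symbol  atomic_number  mass_number  exact_mass  abundance
H	1	1	1.007825	0.999885
H	1	2	2.014102	0.000115
C	6	12	12.000000	0.989300
C	6	13	13.003355	0.010700
N	7	14	14.003074	0.996360
N	7	15	15.000109	0.003640
O	8	16	15.994915	0.997570
O	8	17	16.999132	0.000380
O	8	18	17.999160	0.002050
F	9	19	18.998403	1.000000
Na	11	23	22.989769	1.000000
Si	14	28	27.976927	0.922230
Si	14	29	28.976495	0.046850
Si	14	30	29.973770	0.030920
P	15	31	30.973762	1.000000
S	16	32	31.972071	0.949900
S	16	33	32.971459	0.007500
S	16	34	33.967867	0.042500
S	16	36	35.967081	0.000100
Cl	17	35	34.968853	0.757600
Cl	17	37	36.965903	0.242400
K	19	39	38.963706	0.932581
K	19	40	39.963998	0.000117
K	19	41	40.961825	0.067302
Br	35	79	78.918338	0.506900
Br	35	81	80.916290	0.493100
I	53	127	126.904472	1.000000
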