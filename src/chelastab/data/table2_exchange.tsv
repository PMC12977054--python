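# Exchange thermodynamics per ligand: dG298 (kJ/mol) for [LaL] + Ac3+(aq) = [AcL] + La3+(aq),
# experimental log K_La with its ionic medium, and the derived dlogK / log K_Ac reference
# columns at their printed precision (log K_Ac for BP15C5 printed to one decimal).
# Blank fields mean "not reported" (NO3PA has no experimental La constant).
ligand	dG298_kJmol	dlogK_ref	logK_ac_ref	logK_la	pLa_ref	pAc_ref	medium
DOTA	16.09	-2.82	20.04	22.86	17.4	14.6	0.1 M KCl
DO3APIC	18.79	-3.29	17.88	21.17	16.6	13.3	0.1 M KCl
DOTAM	8.43	-1.48	8.87	10.35	10.8	9.3	0.1 M NaNO3
TETA	10.04	-1.76	9.84	11.60	7.0	6.1	0.1 M KCl
MACROPA	-8.03	1.41	16.40	14.99	15.6	17.0	0.1 M KCl
BP15C5	5.13	-0.90	11.6	12.52	12.4	11.5	0.1 M KCl
BP12C4	11.35	-1.99	14.82	16.81	15.6	13.6	0.1 M KCl
NO3PA	17.88	-3.13				0.15 M NaCl
PYTA	21.09	-3.69	21.09	24.78	22.4	18.7	0.1 M NMe4Cl
OCTAPA	-2.46	0.43	20.35	19.92	19.7	20.1	0.15 M NaCl
TPAEN	4.34	-0.76	18.40	19.16	19.15	18.8	0.15 M NaCl
TPADAC	5.74	-1.01	18.54	19.55	17.1	16.1	0.15 M NaCl
DTPA	17.00	-2.98	16.38	19.36	16.9	13.9	0.1 M NaClO4
TTHA	6.72	-1.18	23.26	24.44	20.1	19.0	0.1 M KNO3
HOPO	9.74	-1.71	14.69	16.40	17.3	15.6	0.1 M KCl
BISPI	17.03	-2.98	20.74	23.72	20.8	17.9	0.1 M KCl
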