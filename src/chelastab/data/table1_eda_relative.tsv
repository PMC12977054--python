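# Relative EDA terms (kJ/mol), dE = E_Ac - E_La, per ligand (aqua ion = H2O row).
# Components: dE_int = dE_elec + dE_pauli + dE_ind + dE_disp; dE_pol = dE_ind + dE_disp.
# Values printed to one decimal; identity residuals up to ~0.15 kJ/mol are rounding.
ligand	dE_int	dE_elec	dE_pauli	dE_ind	dE_disp	dE_pol
H2O	114.0	9.7	252.4	305.4	-453.4	-148.0
DOTA	121.9	-112.0	303.9	1080.5	-1150.5	-70.0
DO3APIC	125.2	-143.9	298.9	1106.9	-1136.7	-29.8
DOTAM	125.5	3.3	288.3	446.0	-612.1	-166.1
TETA	119.1	-125.1	309.0	941.6	-1006.4	-64.8
MACROPA	127.5	6.4	288.1	341.6	-508.6	-167.0
BP15C5	136.4	9.3	298.8	657.2	-829.0	-171.8
BP12C4	120.7	-6.7	284.5	627.0	-784.1	-157.1
NO3PA	143.9	0.1	305.1	826.7	-988.0	-161.3
PYTA	146.0	-97.7	298.3	650.6	-705.3	-54.7
OCTAPA	129.7	-50.2	276.3	765.2	-861.7	-96.4
TPAEN	132.2	-104.0	302.1	937.5	-1003.4	-65.9
TPADAC	133.1	-108.4	306.3	970.5	-1035.2	-64.7
DTPA	79.2	-351.1	282.5	1397.5	-1249.7	147.8
TTHA	-28.3	-629.2	270.3	1317.6	-986.9	330.7
HOPO	148.5	30.9	284.7	583.4	-750.4	-167.0
BISPI	147.9	15.2	309.1	726.2	-902.6	-176.4
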