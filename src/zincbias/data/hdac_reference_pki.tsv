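# Reference affinity table: hydroxamate HDAC inhibitors on isoforms HDAC2/HDAC4/HDAC8.
# All experimental Ki values come from a single competitive binding-assay series (nM);
# pki_exp = -log10(Ki in M). pki_dps / pki_ps are docking-calculated pKi for the
# O-deprotonated (hydroxamate) and protonated (hydroxamic acid) ligand series.
isoform	name	ki_nM	pki_exp	pki_dps	pki_ps
HDAC2	LBH-589	0.65	9.19	8.66	8.50
HDAC2	Trichostatin A	0.65	9.19	7.89	7.68
HDAC2	PXD-101	0.85	9.07	8.54	8.67
HDAC2	LAQ-824	1.40	8.85	8.14	8.90
HDAC2	SAHA	1.60	8.80	7.63	7.10
HDAC2	Scriptaid	2.20	8.66	7.99	7.83
HDAC2	ITF-2357	3.00	8.52	8.36	8.16
HDAC2	Pyroxamide	3.60	8.44	7.60	7.18
HDAC2	SHA	29.00	7.54	7.03	6.64
HDAC2	4-PBHA	430.00	6.37	6.62	6.38
HDAC4	PXD-101	380.00	6.42	7.94	7.62
HDAC4	LBH-589	550.00	6.26	7.64	7.47
HDAC4	ITF-2357	1050.00	5.98	7.68	7.33
HDAC4	Trichostatin A	1400.00	5.85	7.18	6.91
HDAC4	LAQ-824	2250.00	5.65	7.22	6.94
HDAC4	Scriptaid	7500.00	5.12	7.01	6.96
HDAC8	PXD-101	25.00	7.60	8.72	8.34
HDAC8	ITF-2357	39.00	7.41	9.42	9.06
HDAC8	Trichostatin A	45.00	7.35	8.43	7.84
HDAC8	LBH-589	105.00	6.98	8.39	8.00
HDAC8	Scriptaid	105.00	6.98	8.39	8.21
HDAC8	SAHA	250.00	6.60	7.33	6.91
HDAC8	LAQ-824	340.00	6.47	8.09	7.79
HDAC8	SHA	950.00	6.02	7.11	6.79
HDAC8	Pyroxamide	1000.00	6.00	7.45	7.15
HDAC8	4-PBHA	1850.00	5.73	6.98	6.54
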