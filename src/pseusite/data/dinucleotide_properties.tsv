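# Dinucleotide physicochemical properties used by the pseudo dinucleotide
# composition (PseDNC) encoder. Columns: free energy (unified nearest-
# neighbour duplex free energies, kcal/mol), base-stacking energy
# (Ornstein et al. stacking energies, kcal/mol), and hydrophilicity, as
# circulated in the PseDNC literature, with T transcribed to U.
# Values are standardized to zero mean / unit variance over the 16
# dinucleotides at load time. schema_version: 1
dinucleotide	free_energy	stacking_energy	hydrophilicity
AA	-1.00	-5.37	0.04
AC	-1.44	-10.51	0.14
AG	-1.28	-6.78	0.08
AU	-0.88	-6.57	0.14
CA	-1.45	-6.57	0.21
CC	-1.84	-8.26	0.49
CG	-2.17	-9.69	0.35
CU	-1.28	-6.78	0.52
GA	-1.30	-9.81	0.10
GC	-2.24	-14.59	0.26
GG	-1.84	-8.26	0.17
GU	-1.44	-10.51	0.27
UA	-0.58	-3.82	0.21
UC	-1.30	-9.81	0.48
UG	-1.45	-6.57	0.34
UU	-1.00	-5.37	0.44
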