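# xhpi-schema: 1.0
# Toy nonbonded parameter set for the synthetic donor/ring residues used in
# tests and examples.  Charges in elementary units, sigma in nm, epsilon in
# kcal/mol.  Values are generic protein-force-field magnitudes (aliphatic C,
# aromatic C, amide N/O/H); NOT a validated force field.
residue	atom	charge_e	sigma_nm	epsilon_kcal
ALA	CA	0.03	0.3400	0.1094
ALA	CB	-0.27	0.3400	0.1094
ALA	HB1	0.08	0.2650	0.0157
ALA	HB2	0.08	0.2650	0.0157
ALA	HB3	0.08	0.2650	0.0157
ASN	CG	0.55	0.3400	0.0860
ASN	OD1	-0.55	0.2960	0.2100
ASN	ND2	-0.62	0.3250	0.1700
ASN	HD21	0.31	0.1069	0.0157
ASN	HD22	0.31	0.1069	0.0157
PHE	CG	-0.06	0.3400	0.0860
PHE	CD1	-0.12	0.3400	0.0860
PHE	CD2	-0.12	0.3400	0.0860
PHE	CE1	-0.12	0.3400	0.0860
PHE	CE2	-0.12	0.3400	0.0860
PHE	CZ	-0.12	0.3400	0.0860
TYR	CG	-0.06	0.3400	0.0860
TYR	CD1	-0.12	0.3400	0.0860
TYR	CD2	-0.12	0.3400	0.0860
TYR	CE1	-0.12	0.3400	0.0860
TYR	CE2	-0.12	0.3400	0.0860
TYR	CZ	0.11	0.3400	0.0860
TYR	OH	-0.53	0.3070	0.2104
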