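# Dinucleotide structural property scales used for sequence-intrinsic features.
# Best-effort values assembled from the biophysical literature; each scale is
# symmetric under reverse complementation of the dinucleotide.
# a_philicity: A-form propensity (Ivanov & Minchenkova-style scale, a.u.)
# z_dna_stability_energy: Z-form dinucleotide free energy (Ho et al.-style, kcal/mol)
# duplex_disrupt_energy: duplex disruption free energy (Breslauer-style dG, kcal/mol)
# duplex_stability_free_energy: nearest-neighbor duplex dG37 (SantaLucia-style, kcal/mol)
# stacking_energy: base-stacking energy (Ornstein-style, kcal/mol)
# dna_denaturation: dinucleotide melting propensity (Blake & Delcourt-style, a.u.)
# b_dna_twist: B-form helical twist (degrees)
# protein_dna_twist: twist in protein-DNA complexes (Olson-style, degrees)
# propeller_twist: propeller twist (el Hassan & Calladine-style, degrees)
# bending_stiffness: bending force constant (a.u.)
scale	dinucleotide	value
a_philicity	AA	1.00
a_philicity	AC	0.64
a_philicity	AG	1.27
a_philicity	AT	0.53
a_philicity	CA	1.16
a_philicity	CC	0.72
a_philicity	CG	1.11
a_philicity	CT	1.27
a_philicity	GA	0.94
a_philicity	GC	1.41
a_philicity	GG	0.72
a_philicity	GT	0.64
a_philicity	TA	0.66
a_philicity	TC	0.94
a_philicity	TG	1.16
a_philicity	TT	1.00
z_dna_stability_energy	AA	3.90
z_dna_stability_energy	AC	4.60
z_dna_stability_energy	AG	3.40
z_dna_stability_energy	AT	5.90
z_dna_stability_energy	CA	1.30
z_dna_stability_energy	CC	2.40
z_dna_stability_energy	CG	0.70
z_dna_stability_energy	CT	3.40
z_dna_stability_energy	GA	3.40
z_dna_stability_energy	GC	4.00
z_dna_stability_energy	GG	2.40
z_dna_stability_energy	GT	4.60
z_dna_stability_energy	TA	2.50
z_dna_stability_energy	TC	3.40
z_dna_stability_energy	TG	1.30
z_dna_stability_energy	TT	3.90
duplex_disrupt_energy	AA	1.90
duplex_disrupt_energy	AC	1.30
duplex_disrupt_energy	AG	1.60
duplex_disrupt_energy	AT	1.50
duplex_disrupt_energy	CA	1.90
duplex_disrupt_energy	CC	3.10
duplex_disrupt_energy	CG	3.60
duplex_disrupt_energy	CT	1.60
duplex_disrupt_energy	GA	1.60
duplex_disrupt_energy	GC	3.10
duplex_disrupt_energy	GG	3.10
duplex_disrupt_energy	GT	1.30
duplex_disrupt_energy	TA	0.90
duplex_disrupt_energy	TC	1.60
duplex_disrupt_energy	TG	1.90
duplex_disrupt_energy	TT	1.90
duplex_stability_free_energy	AA	-1.00
duplex_stability_free_energy	AC	-1.44
duplex_stability_free_energy	AG	-1.28
duplex_stability_free_energy	AT	-0.88
duplex_stability_free_energy	CA	-1.45
duplex_stability_free_energy	CC	-1.84
duplex_stability_free_energy	CG	-2.17
duplex_stability_free_energy	CT	-1.28
duplex_stability_free_energy	GA	-1.30
duplex_stability_free_energy	GC	-2.24
duplex_stability_free_energy	GG	-1.84
duplex_stability_free_energy	GT	-1.44
duplex_stability_free_energy	TA	-0.58
duplex_stability_free_energy	TC	-1.30
duplex_stability_free_energy	TG	-1.45
duplex_stability_free_energy	TT	-1.00
stacking_energy	AA	-5.37
stacking_energy	AC	-10.51
stacking_energy	AG	-6.78
stacking_energy	AT	-6.57
stacking_energy	CA	-6.57
stacking_energy	CC	-8.26
stacking_energy	CG	-9.69
stacking_energy	CT	-6.78
stacking_energy	GA	-9.81
stacking_energy	GC	-14.59
stacking_energy	GG	-8.26
stacking_energy	GT	-10.51
stacking_energy	TA	-3.82
stacking_energy	TC	-9.81
stacking_energy	TG	-6.57
stacking_energy	TT	-5.37
dna_denaturation	AA	66.51
dna_denaturation	AC	108.80
dna_denaturation	AG	85.12
dna_denaturation	AT	72.29
dna_denaturation	CA	64.92
dna_denaturation	CC	99.31
dna_denaturation	CG	91.56
dna_denaturation	CT	85.12
dna_denaturation	GA	80.38
dna_denaturation	GC	135.83
dna_denaturation	GG	99.31
dna_denaturation	GT	108.80
dna_denaturation	TA	50.11
dna_denaturation	TC	80.38
dna_denaturation	TG	64.92
dna_denaturation	TT	66.51
b_dna_twist	AA	35.62
b_dna_twist	AC	34.40
b_dna_twist	AG	27.70
b_dna_twist	AT	31.50
b_dna_twist	CA	34.50
b_dna_twist	CC	33.67
b_dna_twist	CG	29.80
b_dna_twist	CT	27.70
b_dna_twist	GA	36.90
b_dna_twist	GC	40.00
b_dna_twist	GG	33.67
b_dna_twist	GT	34.40
b_dna_twist	TA	36.00
b_dna_twist	TC	36.90
b_dna_twist	TG	34.50
b_dna_twist	TT	35.62
protein_dna_twist	AA	35.10
protein_dna_twist	AC	31.50
protein_dna_twist	AG	31.90
protein_dna_twist	AT	29.30
protein_dna_twist	CA	37.30
protein_dna_twist	CC	32.90
protein_dna_twist	CG	36.10
protein_dna_twist	CT	31.90
protein_dna_twist	GA	39.30
protein_dna_twist	GC	38.30
protein_dna_twist	GG	32.90
protein_dna_twist	GT	31.50
protein_dna_twist	TA	40.50
protein_dna_twist	TC	39.30
protein_dna_twist	TG	37.30
protein_dna_twist	TT	35.10
propeller_twist	AA	-18.66
propeller_twist	AC	-13.10
propeller_twist	AG	-14.00
propeller_twist	AT	-15.01
propeller_twist	CA	-9.45
propeller_twist	CC	-8.11
propeller_twist	CG	-10.03
propeller_twist	CT	-14.00
propeller_twist	GA	-13.48
propeller_twist	GC	-11.08
propeller_twist	GG	-8.11
propeller_twist	GT	-13.10
propeller_twist	TA	-11.85
propeller_twist	TC	-13.48
propeller_twist	TG	-9.45
propeller_twist	TT	-18.66
bending_stiffness	AA	35.0
bending_stiffness	AC	60.0
bending_stiffness	AG	60.0
bending_stiffness	AT	20.0
bending_stiffness	CA	60.0
bending_stiffness	CC	130.0
bending_stiffness	CG	85.0
bending_stiffness	CT	60.0
bending_stiffness	GA	60.0
bending_stiffness	GC	85.0
bending_stiffness	GG	130.0
bending_stiffness	GT	60.0
bending_stiffness	TA	20.0
bending_stiffness	TC	60.0
bending_stiffness	TG	60.0
bending_stiffness	TT	35.0
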