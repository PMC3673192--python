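column	units	description	source
AN	-	atomic number	periodic table (exact)
AR	angstrom	atomic (metallic) radius	standard physical-chemistry handbook compilation
r	angstrom	Pauling ionic radius of the ion	standard physical-chemistry handbook compilation
rho	g/cm3	density of the elemental metal	standard physical-chemistry handbook compilation
dE0	V	absolute standard electrochemical potential, ion to its first stable reduced state	standard electrochemical series
dIP	eV	ionization step producing the ion from its first reduced state (1st IP for M+, 2nd IP for M2+)	standard ionization-energy tables
Z	-	ion charge (oxidation state)	exact
AN_dIP	-	atomic number : ionization potential ratio	computed AN / dIP
logKOH	-	|log10| of the first hydrolysis constant	aqueous-chemistry stability-constant compilations
MP	degC	melting point of the elemental metal	standard physical-chemistry handbook compilation
pKspCO3	-	-log10 solubility product of the metal carbonate (absent where freely soluble)	solubility-product compilations
sigma_p	-	Pearson softness coefficient	metal-ion softness compilations used in ion-QSAR work
Xm	-	Pauling electronegativity	standard electronegativity tables
Xm2r	-	covalent index	computed Xm^2 * r
Z_AR	1/angstrom	ionic charge : atomic radius ratio	computed Z / AR
Z2_r	1/angstrom	cation polarizing power	computed Z^2 / r
# NOTE: this table is a synthetic stand-in compiled from the handbook-type
# sources above for the 17 study ions; individual cells were not copied from
# any single published supplement and may differ from other compilations in
# the last digit or in the convention chosen (noted in docs/methods.md).
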