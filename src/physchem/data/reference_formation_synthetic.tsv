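# Synthetic gas-phase formation-enthalpy reference table (kJ/mol), version 1.
# SYNTHETIC STAND-IN: these are not tabulated ATcT evaluations.  The values
# were calibrated to be mutually consistent with the packaged raspberry-ketone
# fixture (physchem.synthetic.make_rk_fixture) while staying close to the
# experimental literature for most species; benzyl alcohol and the C5
# auxiliaries absorb the residual inconsistency of the calibration targets
# and deviate from experimental evaluations by up to ~14 kJ/mol.
# Columns: species_id, formula, smiles, delta_f_h (kJ/mol), u (kJ/mol), provenance
species_id	formula	smiles	delta_f_h	u	provenance
methane	CH4	C	-74.52	0.06	literature-consistent, calibrated
methanol	CH4O	CO	-200.71	0.20	literature-consistent, calibrated
phenol	C6H6O	Oc1ccccc1	-96.36	0.60	literature-consistent, calibrated
toluene	C7H8	Cc1ccccc1	50.05	0.60	literature-consistent, calibrated
butan-2-one	C4H8O	CCC(C)=O	-238.60	1.03634	calibrated to fixture
p-cresol	C7H8O	Cc1ccc(O)cc1	-125.18	1.17784	calibrated to fixture
pentan-2-one	C5H10O	CCCC(C)=O	-256.05	1.18545	calibrated to fixture
butanoic-acid	C4H8O2	CCCC(O)=O	-475.89	1.99068	calibrated to fixture
pentanoic-acid	C5H10O2	CCCCC(O)=O	-487.72	0.76164	calibrated to fixture
benzyl-alcohol	C7H8O	OCc1ccccc1	-113.47	1.69779	calibrated to fixture
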