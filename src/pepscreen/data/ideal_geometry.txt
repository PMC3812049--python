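# Ideal covalent geometry for the reduced peptide representation.
# Bond lengths in Angstrom, angles in degrees. One value per bond class;
# values are held rigid during sampling (only torsions move).
bond_n_ca       1.458
bond_ca_c       1.525
bond_c_n        1.329
bond_ca_cb      1.530
bond_side       1.800
angle_n_ca_c    111.0
angle_ca_c_n    116.2
angle_c_n_ca    121.7
angle_n_ca_cb   110.5
angle_side      114.0
# Improper dihedral C-N-CA-CB fixing side-chain branch chirality (degrees).
dihedral_cb     -122.6
# Peptide bond torsion omega, fixed at trans.
omega           180.0
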