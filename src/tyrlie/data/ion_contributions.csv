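# Mean ligand-ion distances (angstrom) and electrostatic interaction energies
# (kcal/mol) of the two active-site Cu2+ ions for each bound ligand.
ligand_id,ion,distance,v_ele
l-DOPA,Cu_A,2.79,-17.63
l-DOPA,Cu_B,4.45,-4.16
l-Tyr,Cu_A,3.75,-10.81
l-Tyr,Cu_B,4.69,-7.39
TRO,Cu_A,2.21,-15.04
TRO,Cu_B,4.73,-1.98
KA,Cu_A,5.27,-5.70
KA,Cu_B,4.82,-11.88
KA1,Cu_A,4.56,-9.37
KA1,Cu_B,5.46,-2.26
KA2,Cu_A,3.09,-8.59
KA2,Cu_B,3.76,-1.42
KA3,Cu_A,3.71,-9.91
KA3,Cu_B,3.68,-7.77
KA4,Cu_A,3.68,-2.50
KA4,Cu_B,3.46,-1.07
KA5,Cu_A,3.59,-5.22
KA5,Cu_B,3.64,-7.47
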