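# Default geometry and charge parameters for the octahedral Cu2+ dummy-atom
# site model. The numeric values below are PLACEHOLDERS chosen only to satisfy
# the model invariants (total charge +2.0 e, axial >= equatorial distance);
# production force-field values must be supplied by the user from a published
# dummy-cation parameterization. All geometry and charge invariants enforced
# by the builder are independent of the specific numbers here.
core_charge: 0.0     # e, on the central Cu core
eq_charge: 0.32      # e, each of the 4 equatorial dummies
ax_charge: 0.36      # e, each of the 2 axial dummies
eq_distance: 0.90    # angstrom, core -> equatorial dummy
ax_distance: 1.10    # angstrom, core -> axial dummy (Jahn-Teller elongated)
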