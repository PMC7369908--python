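# Reference interaction-energy differences (kcal/mol) between bound and free
# states for each tyrosinase ligand, with the published LIE estimates and
# experimental binding free energies. sem columns are the published +/- values.
ligand_id,dV_vdw,dV_vdw_sem,dV_ele,dV_ele_sem,dG_lie1,dG_lie1_sem,dG_lie2,dG_lie2_sem,dG_exp
l-DOPA,-17.95,0.53,-22.93,1.02,-10.79,0.32,-11.20,0.33,
l-Tyr,-12.44,0.37,-20.91,0.82,-9.13,0.24,-9.47,0.22,-9.50
TRO,-12.9,0.19,-15.16,0.97,-7.93,0.53,-7.60,0.48,-8.30
KA,-5.68,0.08,-18.24,0.26,-7.04,0.27,-7.28,0.28,-7.46
KA1,-8.76,0.30,-11.32,0.53,-5.31,0.24,-5.51,0.25,-5.99
KA2,-12.91,0.03,-11.68,0.12,-6.17,0.15,-6.42,0.15,-5.85
KA3,-6.09,0.44,-14.19,0.18,-6.34,0.80,-5.98,0.72,-5.73
KA4,-16.68,0.05,-5.56,0.10,-4.83,0.66,-5.05,0.68,-5.24
KA5,-17.14,0.10,-3.75,0.08,-4.69,0.03,-4.53,0.02,-4.68
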