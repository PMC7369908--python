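# Crystal and MD-averaged metal-partner distances (angstrom) for the binuclear
# Cu site of bacterial tyrosinase with kojic acid bound. role marks the
# Jahn-Teller class of each partner around its ion (axial = elongated).
ion,residue,atom,role,exp_distance,sim_mean,sim_sd
Cu_A,His204,NE2,equatorial,2.09,2.15,0.07
Cu_A,His208,NE2,axial,2.07,2.30,0.07
Cu_A,His231,NE2,equatorial,2.02,2.02,0.11
Cu_A,WT572,O,axial,2.28,2.34,0.07
Cu_A,WT613,O,equatorial,1.96,2.11,0.04
Cu_A,WT657,O,equatorial,1.96,2.12,0.03
Cu_B,His42,NE2,equatorial,2.09,2.00,0.09
Cu_B,His60,NE2,axial,2.07,2.33,0.06
Cu_B,His69,NE2,equatorial,2.02,2.01,0.10
Cu_B,WT610,O,equatorial,1.96,2.11,0.03
Cu_B,WT646,O,equatorial,1.96,2.12,0.03
Cu_B,WT653,O,axial,2.28,2.26,0.06
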