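HETATM    1 CU    CU A   1       0.000   0.000   0.000  1.00  0.00          CU  
ATOM      2  NE2 HIS A   2      -1.212  -1.212  -1.212  1.00  0.00           N  
ATOM      3  NE2 HIS A   3       0.000   2.100   0.000  1.00  0.00           N  
ATOM      4  NE2 HIS A   4       0.000   0.000   2.100  1.00  0.00           N  
HETATM    5  O   HOH A   5       0.000  -2.200   0.000  1.00  0.00           O  
HETATM    6  O   HOH A   6       0.000   0.000  -2.200  1.00  0.00           O  
HETATM    7  O   HOH A   7      -2.200   0.000   0.000  1.00  0.00           O  
HETATM    8 CU    CU A 101       4.200   0.000   0.000  1.00  0.00          CU  
ATOM      9  NE2 HIS A 102       5.412   1.212   1.212  1.00  0.00           N  
ATOM     10  NE2 HIS A 103       4.200   2.100   0.000  1.00  0.00           N  
ATOM     11  NE2 HIS A 104       4.200   0.000   2.100  1.00  0.00           N  
HETATM   12  O   HOH A 105       4.200  -2.200   0.000  1.00  0.00           O  
HETATM   13  O   HOH A 106       4.200   0.000  -2.200  1.00  0.00           O  
HETATM   14  O   HOH A 107       6.400   0.000   0.000  1.00  0.00           O  
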