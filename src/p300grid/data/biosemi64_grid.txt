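# Synthetic default electrode-grid layout (not the original figure's layout):
# the 64-channel BioSemi 10/20 montage projected row-wise onto a 10 x 11 grid.
# Rows run anterior -> posterior (row 0 = forehead), columns left -> right
# (col 0 = left ear side). One "channel row col" triple per line.
# 64 occupied cells, 46 empty cells.
Fp1 0 4
Fpz 0 5
Fp2 0 6
AF7 1 3
AF3 1 4
AFz 1 5
AF4 1 6
AF8 1 7
F7 2 1
F5 2 2
F3 2 3
F1 2 4
Fz 2 5
F2 2 6
F4 2 7
F6 2 8
F8 2 9
FT7 3 1
FC5 3 2
FC3 3 3
FC1 3 4
FCz 3 5
FC2 3 6
FC4 3 7
FC6 3 8
FT8 3 9
T7 4 1
C5 4 2
C3 4 3
C1 4 4
Cz 4 5
C2 4 6
C4 4 7
C6 4 8
T8 4 9
TP7 5 1
CP5 5 2
CP3 5 3
CP1 5 4
CPz 5 5
CP2 5 6
CP4 5 7
CP6 5 8
TP8 5 9
P9 6 0
P7 6 1
P5 6 2
P3 6 3
P1 6 4
Pz 6 5
P2 6 6
P4 6 7
P6 6 8
P8 6 9
P10 6 10
PO7 7 3
PO3 7 4
POz 7 5
PO4 7 6
PO8 7 7
O1 8 4
Oz 8 5
O2 8 6
Iz 9 5
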