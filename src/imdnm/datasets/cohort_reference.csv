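id,sex,age,exclusion,procedure,lobe,side,etiology,engel
A,0,5,1,2,1,1,1,IV
B,1,6,1,2,1,1,1,Ia
C,0,10,3,2,1,1,3,IV
D,1,8,,2,1,0,3,II
E,1,12,3,2,2,0,1,III
F,1,13,,2,5,1,1,II
G,1,6,,1,1,1,3,Ia
H,0,5,,2,2,1,1,IV
I,1,9,,2,2,0,2,IV
J,0,11,,2,2,1,1,Ia
K,0,7,,2,2,1,1,1
L,1,4,,1,5,0,1,1
M,0,3,,1,1,0,2,1
N,1,12,,2,1,0,1,II
O,1,10,3,3,1,1,7,III
P,0,7,3,2,1,1,0,I
Q,0,6,1,3,5,0,6,IV
R,0,5,,1,1,0,2,IV
S,0,5,1,3,1,0,6,III
T,0,15,,1,5,1,6,I-D
U,1,16,3,,,,,
V,1,13,,1,2,1,4,IV
W,0,12,2,,,,,
X,1,9,,2,2,1,3,I
Y,0,8,4,3,5,0,5,I
Z,1,14,1,,,,,
AA,0,8,,1,1,0,1,III
BB,1,6,,1,5,0,5,I
CC,0,12,,3,5,2,5,II
DD,1,13,4,1,1,1,5,IV
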