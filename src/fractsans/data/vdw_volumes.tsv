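# fractsans van der Waals volume table v1
# Atomic vdW volumes in A^3, V = 4/3 pi r^3 with Bondi (1964) radii
# (Alvarez 2013 radii for Ca, Mn, Fe, Co)
# element	volume_A3
H	7.2382
D	7.2382
C	20.5795
N	15.5985
O	14.7102
F	13.3058
NA	48.9966
MG	21.6884
P	24.4290
S	24.4290
CL	22.4493
K	87.1137
CA	51.6327
MN	61.6009
FE	60.8497
CO	57.9058
NI	18.1406
CU	11.4940
ZN	11.2495
SE	28.7309
BR	26.5218
I	32.5150
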