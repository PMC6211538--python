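# fractsans neutron scattering length table v1
# Coherent bound scattering lengths b_c in fm
# Source: Sears (1992) compilation (NIST Center for Neutron Research)
# element	b_coh_fm
H	-3.7390
D	6.6710
C	6.6460
N	9.3600
O	5.8030
F	5.6540
NA	3.6300
MG	5.3750
P	5.1300
S	2.8470
CL	9.5770
K	3.6700
CA	4.7000
MN	-3.7300
FE	9.4500
CO	2.4900
NI	10.3000
CU	7.7180
ZN	5.6800
SE	7.9700
BR	6.7950
I	5.2800
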