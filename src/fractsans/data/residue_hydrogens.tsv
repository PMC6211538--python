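# fractsans implicit-hydrogen template v1
# Bound hydrogens per heavy atom for standard residues (pH ~7.5 protonation)
# n_h: total bound H; n_labile: exchangeable H (bonded to N, O or S)
# residue	atom	n_h	n_labile
ALA	N	1	1
ALA	CA	1	0
ALA	C	0	0
ALA	O	0	0
ALA	OXT	0	0
ALA	CB	3	0
ARG	N	1	1
ARG	CA	1	0
ARG	C	0	0
ARG	O	0	0
ARG	OXT	0	0
ARG	CB	2	0
ARG	CG	2	0
ARG	CD	2	0
ARG	NE	1	1
ARG	CZ	0	0
ARG	NH1	2	2
ARG	NH2	2	2
ASN	N	1	1
ASN	CA	1	0
ASN	C	0	0
ASN	O	0	0
ASN	OXT	0	0
ASN	CB	2	0
ASN	CG	0	0
ASN	OD1	0	0
ASN	ND2	2	2
ASP	N	1	1
ASP	CA	1	0
ASP	C	0	0
ASP	O	0	0
ASP	OXT	0	0
ASP	CB	2	0
ASP	CG	0	0
ASP	OD1	0	0
ASP	OD2	0	0
CYS	N	1	1
CYS	CA	1	0
CYS	C	0	0
CYS	O	0	0
CYS	OXT	0	0
CYS	CB	2	0
CYS	SG	1	1
GLN	N	1	1
GLN	CA	1	0
GLN	C	0	0
GLN	O	0	0
GLN	OXT	0	0
GLN	CB	2	0
GLN	CG	2	0
GLN	CD	0	0
GLN	OE1	0	0
GLN	NE2	2	2
GLU	N	1	1
GLU	CA	1	0
GLU	C	0	0
GLU	O	0	0
GLU	OXT	0	0
GLU	CB	2	0
GLU	CG	2	0
GLU	CD	0	0
GLU	OE1	0	0
GLU	OE2	0	0
GLY	N	1	1
GLY	CA	2	0
GLY	C	0	0
GLY	O	0	0
GLY	OXT	0	0
HIS	N	1	1
HIS	CA	1	0
HIS	C	0	0
HIS	O	0	0
HIS	OXT	0	0
HIS	CB	2	0
HIS	CG	0	0
HIS	ND1	1	1
HIS	CD2	1	0
HIS	CE1	1	0
HIS	NE2	0	0
ILE	N	1	1
ILE	CA	1	0
ILE	C	0	0
ILE	O	0	0
ILE	OXT	0	0
ILE	CB	1	0
ILE	CG1	2	0
ILE	CG2	3	0
ILE	CD1	3	0
LEU	N	1	1
LEU	CA	1	0
LEU	C	0	0
LEU	O	0	0
LEU	OXT	0	0
LEU	CB	2	0
LEU	CG	1	0
LEU	CD1	3	0
LEU	CD2	3	0
LYS	N	1	1
LYS	CA	1	0
LYS	C	0	0
LYS	O	0	0
LYS	OXT	0	0
LYS	CB	2	0
LYS	CG	2	0
LYS	CD	2	0
LYS	CE	2	0
LYS	NZ	3	3
MET	N	1	1
MET	CA	1	0
MET	C	0	0
MET	O	0	0
MET	OXT	0	0
MET	CB	2	0
MET	CG	2	0
MET	SD	0	0
MET	CE	3	0
MSE	N	1	1
MSE	CA	1	0
MSE	C	0	0
MSE	O	0	0
MSE	OXT	0	0
MSE	CB	2	0
MSE	CG	2	0
MSE	SE	0	0
MSE	CE	3	0
PHE	N	1	1
PHE	CA	1	0
PHE	C	0	0
PHE	O	0	0
PHE	OXT	0	0
PHE	CB	2	0
PHE	CG	0	0
PHE	CD1	1	0
PHE	CD2	1	0
PHE	CE1	1	0
PHE	CE2	1	0
PHE	CZ	1	0
PRO	N	0	0
PRO	CA	1	0
PRO	C	0	0
PRO	O	0	0
PRO	OXT	0	0
PRO	CB	2	0
PRO	CG	2	0
PRO	CD	2	0
SER	N	1	1
SER	CA	1	0
SER	C	0	0
SER	O	0	0
SER	OXT	0	0
SER	CB	2	0
SER	OG	1	1
THR	N	1	1
THR	CA	1	0
THR	C	0	0
THR	O	0	0
THR	OXT	0	0
THR	CB	1	0
THR	OG1	1	1
THR	CG2	3	0
TRP	N	1	1
TRP	CA	1	0
TRP	C	0	0
TRP	O	0	0
TRP	OXT	0	0
TRP	CB	2	0
TRP	CG	0	0
TRP	CD1	1	0
TRP	CD2	0	0
TRP	NE1	1	1
TRP	CE2	0	0
TRP	CE3	1	0
TRP	CZ2	1	0
TRP	CZ3	1	0
TRP	CH2	1	0
TYR	N	1	1
TYR	CA	1	0
TYR	C	0	0
TYR	O	0	0
TYR	OXT	0	0
TYR	CB	2	0
TYR	CG	0	0
TYR	CD1	1	0
TYR	CD2	1	0
TYR	CE1	1	0
TYR	CE2	1	0
TYR	CZ	0	0
TYR	OH	1	1
VAL	N	1	1
VAL	CA	1	0
VAL	C	0	0
VAL	O	0	0
VAL	OXT	0	0
VAL	CB	1	0
VAL	CG1	3	0
VAL	CG2	3	0
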