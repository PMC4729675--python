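# Default coarse-grained bead mapping.
# Columns: residue_name, bead_name, role, type_code, charge, source_atoms (comma-joined).
# Nucleotides: 1 phosphate bead + 2 sugar/backbone beads + 3 (pyrimidine) or
# 4 (purine) base beads -> 6 or 7 beads per nucleotide.
# Amino acids: 2 mainchain beads + 1-2 sidechain beads -> 3 or 4 beads.
# GLY carries a CA pseudo-sidechain bead so every residue has >= 3 beads.
# The base-atom partition is an editable approximation: only the bead counts
# and the phosphate/backbone/base roles are fixed by the model.
U	PHO	phosphate	1	-0.50	P,OP1,OP2,O5'
U	SG1	sugar	2	0.00	C5',C4'
U	SG2	sugar	3	0.00	C3',C2',C1'
U	BS1	base	10	0.00	N1,C2,O2
U	BS2	base	11	0.00	N3,C4,O4
U	BS3	base	12	0.00	C5,C6
C	PHO	phosphate	1	-0.50	P,OP1,OP2,O5'
C	SG1	sugar	2	0.00	C5',C4'
C	SG2	sugar	3	0.00	C3',C2',C1'
C	BS1	base	13	0.00	N1,C2,O2
C	BS2	base	14	0.00	N3,C4,N4
C	BS3	base	15	0.00	C5,C6
A	PHO	phosphate	1	-0.50	P,OP1,OP2,O5'
A	SG1	sugar	2	0.00	C5',C4'
A	SG2	sugar	3	0.00	C3',C2',C1'
A	BS1	base	20	0.00	N9,C4
A	BS2	base	21	0.00	N7,C8
A	BS3	base	22	0.00	C5,C6,N6
A	BS4	base	23	0.00	N1,C2,N3
G	PHO	phosphate	1	-0.50	P,OP1,OP2,O5'
G	SG1	sugar	2	0.00	C5',C4'
G	SG2	sugar	3	0.00	C3',C2',C1'
G	BS1	base	24	0.00	N9,C4
G	BS2	base	25	0.00	N7,C8
G	BS3	base	26	0.00	C5,C6,O6
G	BS4	base	27	0.00	N1,C2,N3,N2
ALA	MN	mainchain	30	0.00	N,CA
ALA	MC	mainchain	31	0.00	C,O
ALA	SD1	sidechain	40	0.00	CB
ARG	MN	mainchain	30	0.00	N,CA
ARG	MC	mainchain	31	0.00	C,O
ARG	SD1	sidechain	41	0.00	CB,CG,CD
ARG	SD2	sidechain	42	0.30	NE,CZ,NH1,NH2
ASN	MN	mainchain	30	0.00	N,CA
ASN	MC	mainchain	31	0.00	C,O
ASN	SD1	sidechain	43	0.00	CB,CG,OD1,ND2
ASP	MN	mainchain	30	0.00	N,CA
ASP	MC	mainchain	31	0.00	C,O
ASP	SD1	sidechain	44	-0.30	CB,CG,OD1,OD2
CYS	MN	mainchain	30	0.00	N,CA
CYS	MC	mainchain	31	0.00	C,O
CYS	SD1	sidechain	45	0.00	CB,SG
GLN	MN	mainchain	30	0.00	N,CA
GLN	MC	mainchain	31	0.00	C,O
GLN	SD1	sidechain	46	0.00	CB,CG
GLN	SD2	sidechain	47	0.00	CD,OE1,NE2
GLU	MN	mainchain	30	0.00	N,CA
GLU	MC	mainchain	31	0.00	C,O
GLU	SD1	sidechain	48	0.00	CB,CG
GLU	SD2	sidechain	49	-0.30	CD,OE1,OE2
GLY	MN	mainchain	30	0.00	N,CA
GLY	MC	mainchain	31	0.00	C,O
GLY	SD1	sidechain	50	0.00	CA
HIS	MN	mainchain	30	0.00	N,CA
HIS	MC	mainchain	31	0.00	C,O
HIS	SD1	sidechain	51	0.00	CB,CG
HIS	SD2	sidechain	52	0.10	ND1,CD2,CE1,NE2
ILE	MN	mainchain	30	0.00	N,CA
ILE	MC	mainchain	31	0.00	C,O
ILE	SD1	sidechain	53	0.00	CB,CG1,CG2,CD1
LEU	MN	mainchain	30	0.00	N,CA
LEU	MC	mainchain	31	0.00	C,O
LEU	SD1	sidechain	54	0.00	CB,CG,CD1,CD2
LYS	MN	mainchain	30	0.00	N,CA
LYS	MC	mainchain	31	0.00	C,O
LYS	SD1	sidechain	55	0.00	CB,CG,CD
LYS	SD2	sidechain	56	0.30	CE,NZ
MET	MN	mainchain	30	0.00	N,CA
MET	MC	mainchain	31	0.00	C,O
MET	SD1	sidechain	57	0.00	CB,CG
MET	SD2	sidechain	58	0.00	SD,CE
PHE	MN	mainchain	30	0.00	N,CA
PHE	MC	mainchain	31	0.00	C,O
PHE	SD1	sidechain	59	0.00	CB,CG
PHE	SD2	sidechain	60	0.00	CD1,CD2,CE1,CE2,CZ
PRO	MN	mainchain	30	0.00	N,CA
PRO	MC	mainchain	31	0.00	C,O
PRO	SD1	sidechain	61	0.00	CB,CG,CD
SER	MN	mainchain	30	0.00	N,CA
SER	MC	mainchain	31	0.00	C,O
SER	SD1	sidechain	62	0.00	CB,OG
THR	MN	mainchain	30	0.00	N,CA
THR	MC	mainchain	31	0.00	C,O
THR	SD1	sidechain	63	0.00	CB,OG1,CG2
TRP	MN	mainchain	30	0.00	N,CA
TRP	MC	mainchain	31	0.00	C,O
TRP	SD1	sidechain	64	0.00	CB,CG,CD1
TRP	SD2	sidechain	65	0.00	CD2,NE1,CE2,CE3,CZ2,CZ3,CH2
TYR	MN	mainchain	30	0.00	N,CA
TYR	MC	mainchain	31	0.00	C,O
TYR	SD1	sidechain	66	0.00	CB,CG
TYR	SD2	sidechain	67	0.00	CD1,CD2,CE1,CE2,CZ,OH
VAL	MN	mainchain	30	0.00	N,CA
VAL	MC	mainchain	31	0.00	C,O
VAL	SD1	sidechain	68	0.00	CB,CG1,CG2
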