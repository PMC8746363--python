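# Atom typing for the 20 canonical residues (heavy atoms only).
# charge: united-atom partial charge (polar-hydrogen charge folded into the
# carrier heavy atom).  bases: bonded heavy atoms used to infer the polar-H
# direction for donors (antecedent/bisector rule); '-' when not a donor.
# Backbone rows use residue '*' and are shared by all residues unless a
# residue-specific row overrides them (PRO N, GLY CA).
res	atom	type	charge	bases
*	N	Nbb	-0.25	CA
*	CA	CH1	0.10	-
*	C	CObb	0.55	-
*	O	OCbb	-0.40	-
*	OXT	OOC	-0.50	-
ALA	CB	CH3	0.00	-
ARG	CB	CH2	0.00	-
ARG	CG	CH2	0.00	-
ARG	CD	CH2	0.10	-
ARG	NE	Narg	0.25	CD,CZ
ARG	CZ	CH0	0.20	-
ARG	NH1	Narg	0.225	CZ
ARG	NH2	Narg	0.225	CZ
ASN	CB	CH2	0.00	-
ASN	CG	CObb	0.25	-
ASN	OD1	ONH2	-0.55	-
ASN	ND2	NH2O	0.30	CG
ASP	CB	CH2	0.00	-
ASP	CG	CObb	0.20	-
ASP	OD1	OOC	-0.60	-
ASP	OD2	OOC	-0.60	-
CYS	CB	CH2	0.00	-
CYS	SG	SH1	0.00	-
GLN	CB	CH2	0.00	-
GLN	CG	CH2	0.00	-
GLN	CD	CObb	0.25	-
GLN	OE1	ONH2	-0.55	-
GLN	NE2	NH2O	0.30	CD
GLU	CB	CH2	0.00	-
GLU	CG	CH2	0.00	-
GLU	CD	CObb	0.20	-
GLU	OE1	OOC	-0.60	-
GLU	OE2	OOC	-0.60	-
GLY	CA	CH2	0.10	-
HIS	CB	CH2	0.00	-
HIS	CG	CH0	0.00	-
HIS	ND1	Nhis	-0.10	-
HIS	CD2	aroC	0.00	-
HIS	CE1	aroC	0.10	-
HIS	NE2	Ntrp	0.00	CD2,CE1
ILE	CB	CH1	0.00	-
ILE	CG1	CH2	0.00	-
ILE	CG2	CH3	0.00	-
ILE	CD1	CH3	0.00	-
LEU	CB	CH2	0.00	-
LEU	CG	CH1	0.00	-
LEU	CD1	CH3	0.00	-
LEU	CD2	CH3	0.00	-
LYS	CB	CH2	0.00	-
LYS	CG	CH2	0.00	-
LYS	CD	CH2	0.00	-
LYS	CE	CH2	0.20	-
LYS	NZ	Nlys	0.80	CE
MET	CB	CH2	0.00	-
MET	CG	CH2	0.00	-
MET	SD	S	0.00	-
MET	CE	CH3	0.00	-
PHE	CB	CH2	0.00	-
PHE	CG	CH0	0.00	-
PHE	CD1	aroC	0.00	-
PHE	CD2	aroC	0.00	-
PHE	CE1	aroC	0.00	-
PHE	CE2	aroC	0.00	-
PHE	CZ	aroC	0.00	-
PRO	N	Npro	-0.10	-
PRO	CB	CH2	0.00	-
PRO	CG	CH2	0.00	-
PRO	CD	CH2	0.10	-
SER	CB	CH2	0.25	-
SER	OG	OH	-0.25	CB
THR	CB	CH1	0.25	-
THR	OG1	OH	-0.25	CB
THR	CG2	CH3	0.00	-
TRP	CB	CH2	0.00	-
TRP	CG	CH0	0.00	-
TRP	CD1	aroC	0.10	-
TRP	CD2	CH0	0.00	-
TRP	NE1	Ntrp	-0.10	CD1,CE2
TRP	CE2	CH0	0.00	-
TRP	CE3	aroC	0.00	-
TRP	CZ2	aroC	0.00	-
TRP	CZ3	aroC	0.00	-
TRP	CH2	aroC	0.00	-
TYR	CB	CH2	0.00	-
TYR	CG	CH0	0.00	-
TYR	CD1	aroC	0.00	-
TYR	CD2	aroC	0.00	-
TYR	CE1	aroC	0.00	-
TYR	CE2	aroC	0.00	-
TYR	CZ	CH0	0.25	-
TYR	OH	OH	-0.25	CZ
VAL	CB	CH1	0.00	-
VAL	CG1	CH3	0.00	-
VAL	CG2	CH3	0.00	-
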