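# Rose-style mean maximum solvent accessibility per residue (Å²),
# used to convert DSSP absolute exposed areas to relative accessibility.
# residue	max_acc
ALA	118.1
ARG	256.0
ASN	165.5
ASP	158.7
CYS	146.1
GLN	193.2
GLU	186.2
GLY	88.1
HIS	202.5
ILE	181.0
LEU	193.1
LYS	225.8
MET	203.4
PHE	222.8
PRO	146.8
SER	129.8
THR	152.5
TRP	266.3
TYR	236.8
VAL	164.5
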