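# Representative heme and heme-like ligand chemical component codes.
# Structures carrying any of these are not accepted as apo forms.
# Users may supply their own, larger exclusion table; HEM and HEC are
# always included by the loader regardless of table contents.
# code	label
HEM	protoporphyrin IX containing Fe (heme b)
HEC	heme c
HEA	heme a
HEB	heme b (alternate code)
HEO	heme o
HAS	heme-As
HDD	cis-heme d hydroxychlorin gamma-spirolactone
HDM	dimethylated heme
DHE	heme d
DDH	deuteroheme
HNI	protoporphyrin IX containing Ni
HIF	dihydroxy-protoporphyrin IX containing Fe
VER	verdoheme
SRM	siroheme
MHM	meso-heme
HME	heme modified with ethylene glycol
HFM	hydroxymethyl-substituted heme
ZNH	protoporphyrin IX containing Zn
COH	protoporphyrin IX containing Co
MNH	protoporphyrin IX containing Mn
MNR	Mn(III) protoporphyrin IX
MP1	meso-porphyrin containing Fe
PP9	protoporphyrin IX
PNI	porphyrin containing Ni
CLN	chlorin
BCL	bacteriochlorophyll a
CLA	chlorophyll a
1FH	di-heme
2FH	di-heme analogue
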