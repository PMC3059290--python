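# SCOP fold census of the annotated subset of a non-redundant
# heme-binding chain dataset (published survey values, consumed as
# external input; chains without SCOP annotation are not listed).
fold_id	n_chains	fold_name
a.104	9	Cytochrome P450
a.1	14	Globin-like
a.123	1	Nuclear receptor ligand-binding domain
a.126	1	Serum albumin-like
a.132	2	Heme oxygenase-like
a.138	8	Multiheme cytochromes
a.24	2	Four-helical up-and-down bundle
a.266	2	Indolic compounds 2,3-dioxygenase-like
a.3	9	Cytochrome c
a.39	1	EF Hand-like
a.45	1	GST C-terminal domain-like
a.93	5	Heme-dependent peroxidases
b.1	4	Immunoglobulin-like beta-sandwich
b.2	1	Common fold of diphtheria toxin/transcription factors
b.60	2	Lipocalins
b.66	1	4-bladed beta-propeller
b.82	1	Double-stranded beta-helix
c.150	1	EreA/ChaN-like
c.47	1	Thioredoxin fold
c.79	1	Tryptophan synthase beta subunit-like PLP-dependent enzymes
c.92	1	Chelatase-like
d.110	1	Profilin-like
d.120	1	Cytochrome b5-like heme/steroid binding domain
d.151	1	DNase I-like
d.174	1	Nitric oxide (NO) synthase oxygenase domain
d.278	2	Ligand-binding domain in NO signalling and Golgi transport
d.58	3	Ferredoxin-like
e.5	2	Heme-dependent catalase-like
e.62	1	Heme iron utilization protein-like
f.21	5	Heme-binding four-helical bundle
f.24	1	Cytochrome c oxidase subunit I-like
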