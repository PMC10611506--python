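allele	location_on_protein	codon_position	ref_aa	ref_property	alt_aa	alt_property	score	aa_change	property_change	binding_site	eplet_effect
A*03:452	Antigen-binding site, α2	144	Lys	Basic	Gln	Polar uncharged	++++	1	1	1	1
A*26:203	Leader peptide	-15	Val	Nonpolar aliphatic	Leu	Nonpolar aliphatic	+	1	0	0	0
B*15:675	Leader peptide	-9	Ala	Nonpolar aliphatic	Val	Nonpolar aliphatic	+	1	0	0	0
B*48:55	Extracellular arm, α3	228	Thr	Polar uncharged	Ala	Nonpolar aliphatic	++	1	1	0	0
B*56:88	Antigen-binding site, α2	116	Leu	Nonpolar aliphatic	Phe	Nonpolar aromatic	++++	1	1	1	1
C*05:277	Cytoplasmic tail	340	Cys	Polar uncharged	Ser	Polar uncharged	+	1	0	0	0
C*07:1041	Antigen binding site, α1	17	Arg	Basic	Ser	Polar uncharged	++++	1	1	1	1
C*07:1043	Antigen binding site, α1	60	Trp	Nonpolar aromatic	Gly	Nonpolar aliphatic	+++	1	1	1	0
DPA1*01:106	Leader peptide	-30	Arg	Basic	His	Basic	+	1	0	0	0
DPA1*01:136	Extracellular arm, α2	149	His	Basic	Arg	Basic	+	1	0	0	0
DPA1*01:60	Transmembrane/cytoplasmic tail	224	Arg	Basic	Trp	Nonpolar aromatic	++	1	1	0	0
DPA1*02:96	Transmembrane/cytoplasmic tail	213	Ile	Nonpolar aliphatic	Phe	Nonpolar aromatic	++	1	1	0	0
DPB1*1088:01	Transmembrane	194	Gln	Polar uncharged	Arg	Basic	++	1	1	0	0
DRB1*14:249	Antigen-binding site, β1	6	Arg	Basic	Cys	Polar uncharged	++++	1	1	1	1
DRB5*01:130	Extracellular arm, β2	160	Met	Nonpolar aliphatic	Ile	Nonpolar aliphatic	+	1	0	0	0
DRB5*02:37	Extracellular arm, β2	150	Asn	Polar uncharged	Ser	Polar uncharged	+	1	0	0	0
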