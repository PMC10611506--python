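allele	mutation_type	exon	location_on_protein	ref_base	alt_base	genomic_position
A*03:452	Missense	3	Antigen-binding site, α2	A	C	873
A*26:203	Missense	1	Leader peptide	G	C	28
B*15:675	Missense	1	Leader peptide	C	T	47
B*48:01:12	Silent	3	Antigen-binding site, α2	C	T	736
B*48:55	Missense	4	α3 extracellular arm	A	G	1701
B*56:88	Missense	3	Antigen-binding site, α2	A	C	793
C*05:277	Missense	7	Cytoplasmic tail	G	C	2721
C*07:1041	Missense	2	Antigen-binding site, α1	C	A	256
C*07:1043	Missense	2	Antigen-binding site, α1	T	G	385
DPA1*01:03:38:02	Silent	1	Leader peptide	C	T	51
DPA1*01:03:45	Silent	3	α2 extracellular arm	C	T	4506
DPA1*01:106	Missense	1	Leader peptide	G	A	5
DPA1*01:136	Missense	3	α2 extracellular arm	A	G	4463
DPA1*01:137N	Nonsense	1	Leader peptide	C	T	79
DPA1*01:60	Missense	4	Transmembrane/cytoplasmic tail	C	T	4901
DPA1*02:02:13	Silent	4	Transmembrane/cytoplasmic tail	T	C	4876
DPA1*02:96	Missense	4	Transmembrane/cytoplasmic tail	A	T	4850
DPB1*1088:01	Missense	4	Transmembrane	A	G	9701
DQA1*01:01:09:02	Silent	1	Leader peptide	C	G	36
DQA1*01:02:15	Silent	1	Leader peptide	C	T	48
DQA1*01:02:16	Silent	2	Antigen-binding site, α1	C	A	3976
DQA1*01:04:08	Silent	3	α2 extracellular arm	C	T	4548
DQA1*02:01:15Q	Silent	2	Antigen-binding site, α1	C	T	3809
DQA1*04:01:07	Silent	1	Leader peptide	C	T	48
DQA1*05:05:16	Silent	1	Leader peptide	T	A	69
DRB1*14:249	Missense	2	Antigen-binding site, β1	C	T	8091
DRB1*14:54:12	Silent	3	β2 extracellular arm	A	G	10752
DRB5*01:130	Missense	3	β2 extracellular arm	G	T	10808
DRB5*02:37	Missense	3	β2 extracellular arm	A	G	10732
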