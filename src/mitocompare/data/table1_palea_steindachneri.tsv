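accession	OL405264
length	16811
name	element_class	strand	start	end	anticodon	start_codon	stop_codon
tRNA-Phe	tRNA	L	1	69	GAA	.	.
12S-rRNA	rRNA	L	70	1045	.	.	.
tRNA-Val	tRNA	L	1044	1112	UAC	.	.
16S-rRNA	rRNA	L	1113	2719	.	.	.
tRNA-Leu	tRNA	L	2720	2795	UAA	.	.
nad1	PCG	L	2796	3767	.	ATG	TAG
tRNA-Ile	tRNA	L	3767	3836	GAU	.	.
tRNA-Gln	tRNA	H	3836	3906	UUG	.	.
tRNA-Met	tRNA	L	3906	3974	CAU	.	.
nad2	PCG	L	3975	5015	.	ATG	TAG
tRNA-Trp	tRNA	L	5014	5087	UCA	.	.
tRNA-Ala	tRNA	H	5096	5164	UGC	.	.
tRNA-Asn	tRNA	H	5166	5239	GUU	.	.
tRNA-Cys	tRNA	H	5269	5334	GCA	.	.
tRNA-Tyr	tRNA	H	5335	5401	GUA	.	.
cox1	PCG	L	5403	6947	.	GTG	AGA
tRNA-Ser	tRNA	H	6943	7013	UGA	.	.
tRNA-Asp	tRNA	L	7014	7082	GUC	.	.
cox2	PCG	L	7083	7769	.	ATG	TAA
tRNA-Lys	tRNA	L	7771	7843	UUU	.	.
atp8	PCG	L	7845	8009	.	ATG	TAA
atp6	PCG	L	8000	8683	.	ATG	TAA
cox3	PCG	L	8683	9466	.	ATG	T--
tRNA-Gly	tRNA	L	9467	9535	UCC	.	.
nad3	PCG	L	9536	9885	.	ATG	T--
tRNA-Arg	tRNA	L	9886	9955	UCG	.	.
nad4L	PCG	L	9956	10252	.	ATG	TAA
nad4	PCG	L	10246	11626	.	ATG	T--
tRNA-His	tRNA	L	11627	11696	GUG	.	.
tRNA-Ser	tRNA	L	11697	11758	GCU	.	.
tRNA-Leu	tRNA	L	11758	11830	UAG	.	.
nad5	PCG	L	11831	13609	.	ATG	TAA
nad6	PCG	H	13605	14129	.	ATG	AGA
tRNA-Glu	tRNA	H	14130	14197	UUC	.	.
cytb	PCG	L	14201	15340	.	ATG	TAA
tRNA-Thr	tRNA	L	15344	15417	UGU	.	.
tRNA-Pro	tRNA	H	15437	15506	UGG	.	.
control_region	CR	L	15507	16811	.	.	.
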