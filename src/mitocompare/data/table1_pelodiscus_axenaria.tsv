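accession	OR805132
length	17143
name	element_class	strand	start	end	anticodon	start_codon	stop_codon
tRNA-Phe	tRNA	L	1	68	GAA	.	.
12S-rRNA	rRNA	L	69	1045	.	.	.
tRNA-Val	tRNA	L	1046	1115	UAC	.	.
16S-rRNA	rRNA	L	1116	2714	.	.	.
tRNA-Leu	tRNA	L	2715	2791	UAA	.	.
nad1	PCG	L	2792	3763	.	ATG	TAG
tRNA-Ile	tRNA	L	3763	3832	GAU	.	.
tRNA-Gln	tRNA	H	3832	3902	UUG	.	.
tRNA-Met	tRNA	L	3902	3970	CAU	.	.
nad2	PCG	L	3971	5011	.	ATG	TAG
tRNA-Trp	tRNA	L	5010	5082	UCA	.	.
tRNA-Ala	tRNA	H	5094	5162	UGC	.	.
tRNA-Asn	tRNA	H	5164	5237	GUU	.	.
tRNA-Cys	tRNA	H	5269	5333	GCA	.	.
tRNA-Tyr	tRNA	H	5334	5399	GUA	.	.
cox1	PCG	L	5401	6945	.	GTG	AGA
tRNA-Ser	tRNA	H	6941	7011	UGA	.	.
tRNA-Asp	tRNA	L	7013	7081	GUC	.	.
cox2	PCG	L	7082	7768	.	ATG	TAA
tRNA-Lys	tRNA	L	7769	7841	UUU	.	.
atp8	PCG	L	7843	8007	.	ATG	TAA
atp6	PCG	L	7998	8681	.	ATG	TAA
cox3	PCG	L	8681	9464	.	ATG	T--
tRNA-Gly	tRNA	L	9465	9534	UCC	.	.
nad3	PCG	L	9535	9884	.	ATG	T--
tRNA-Arg	tRNA	L	9885	9955	UCG	.	.
nad4L	PCG	L	9956	10252	.	ATG	TAA
nad4	PCG	L	10246	11626	.	ATG	T--
tRNA-His	tRNA	L	11627	11696	GUG	.	.
tRNA-Ser	tRNA	L	11697	11758	GCU	.	.
tRNA-Leu	tRNA	L	11758	11829	UAG	.	.
nad5	PCG	L	11830	13608	.	ATG	TAA
nad6	PCG	H	13604	14128	.	ATG	AGA
tRNA-Glu	tRNA	H	14129	14196	UUC	.	.
cytb	PCG	L	14200	15339	.	ATG	TAA
tRNA-Thr	tRNA	L	15343	15416	UGU	.	.
tRNA-Pro	tRNA	H	15431	15501	UGG	.	.
control_region	CR	L	15502	17143	.	.	.
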