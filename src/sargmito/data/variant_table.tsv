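position	locus	nt_fluitans	nt_natansI	nt_natansVIII	aa_chain
1279	23S rRNA	C	T	T	–
1883	23S rRNA	C	T	C	–
2658	23S rRNA	A	G	G	–
2662	Intergenic Region	C	T	T	–
2688	Intergenic Region	C	T	T	–
2691	Intergenic Region	G	T	T	–
2714	Intergenic Region	G	T	T	–
2715	Intergenic Region	A	T	T	–
2716	Intergenic Region	T	A	A	–
2717	Intergenic Region	T	A	A	–
2718	Intergenic Region	A	T	T	–
2719	Intergenic Region	A	C	C	–
4629	rpl6	C	T	T	Ala > Ala
4928	rps2	C	T	T	Pro > Pro
5147	rps2	C	T	T	Thr > Thr
5424	rps4	G	A	A	Ala > Ala
5470	rps4	T	C	C	Leu > Leu
5491	rps4	A	G	G	Ile > Val
5832	rps4	C	T	T	Pro > Pro
6097	Intergenic Region	T	C	C	–
6805	nad1	T	C	C	Val > Val
7033	nad1	C	T	T	Arg > Arg
7237	tatC	T	A	A	Ile > Phe
7720	tatC	G	A	A	Leu > Leu
7837	Intergenic Region	A	T	T	–
7903	trnW(cca)	A	G	G	–
8090	orf39	T	C	C	Phe > Ser
8250	trnQ(uug)	G	A	A	–
8438	rps12	G	A	A	Ala > Thr
8857	rps7	A	G	G	Ser > Gly
9030	rps7	A	T	T	Ile > Ile
9153	rps7	A	G	G	Ala > Ala
9863	rpl14	C	A	A	Val > Val
10018	rpl14	C	T	T	Ser > Leu
10313	rpl5	C	C	T	Pro > Ser
10783	orf129	C	A	A	Glu > Stop
12021	rps3	A	T	T	Ser > Ser
12429	rps19	G	G	T	Gln > Lys
12821	rpl2	T	C	C	Gly > Gly
12878	rpl2	G	T	T	Ala > Ala
13502	rps13	G	G	T	Ala > Ser
13537	rps13	T	C	C	Phe > Phe
13583	rps13	G	C	C	Val > Leu
14111	rps11	T	C	C	Val > Val
14466	cox3	A	G	G	Leu > Leu
14516	cox3	G	A	G	Gly > Asp > Gly
15108	cox3	G	A	A	Gly > Gly
15249	Intergenic Spacer	G	C	C	–
17135	nad2	C	T	T	Val > Val
18237	cox1	T	C	C	Phe > Phe
18645	cox1	G	T	T	Thr > Thr
19527	Intergenic Spacer	T	C	C	–
19698	nad9	T	C	C	Tyr > His
20527	cob	T	C	C	Gly > Gly
21649	cox2	A	G	G	Leu > Leu
21693	cox2	C	G	G	Thr > Ser
21780	cox2	G	C	C	Gly > Ala
21940	cox2	A	G	G	Leu > Leu
22037	cox2	C	T	T	Leu > Leu
22216	cox2	A	T	T	Ser > Ser
22453	cox2	C	T	T	Thr > Thr
22469	cox2	G	A	A	Glu > Lys
22474	cox2	T	C	C	Ser > Ser
23156	cox2	C	T	T	Pro > Ser
23290	cox2	G	A	A	Val > Val
23294	cox2	T	G	G	Tyr > Asp
23577	cox2	G	A	A	Arg > Lys
23856	cox2	T	C	C	Leu > Pro
24568	cox2	T	A	A	Asp > Glu
24665	nad4	G	A	A	Gly > Glu
24706	nad4	T	G	G	Ser > Ala
24861	nad4	C	T	T	Thr > Thr
26136	trnl(uau)	T	A	A	–
26272	nad5	T	C	C	Cys > Cys
26536	nad5	C	T	T	Phe > Phe
26926	nad5	A	T	T	Val > Val
26962	nad5	T	A	A	Ala > Ala
27508	nad5	C	T	T	Pro > Pro
28323	nad6	G	A	A	Ala > Ala
28444	nad6	T	T	A	Phe > Ile
28463	nad6	C	G	G	Thr > Ser
28656	nad6	C	T	T	Thr > Thr
28890	nad6	A	G	G	Leu > Leu
28895	nad6	T	G	G	Leu > Trp
29053	nad11	T	C	C	Asn > Asn
29299	nad11	A	T	T	Leu > Phe
29518	nad11	C	T	T	Cys > Cys
29976	rps14	G	A	A	Ser > Asn
30082	rps14	G	A	A	Arg > Arg
30958	rps10	T	A	A	Leu > Leu
31048	rps10	C	T	T	Ser > Ser
31120	rps10	G	C	C	Lys > Asn
31578	Intergenic Spacer	T	A	A	–
31920	16S rRNA	A	A	C	–
32415	16S rRNA	C	T	T	–
33027	16S rRNA	G	A	A	–
33828	nad7	C	A	A	Leu > Leu
34589	nad7	G	A	A	Stop > Stop
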