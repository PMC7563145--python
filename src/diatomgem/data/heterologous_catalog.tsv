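# Heterologous pathway modules for maximum-theoretical-yield screening.
# Routes are lumped multi-step pathways anchored on host metabolites
# (pyruvate, triose phosphate, acetyl units, glutamate) so that yields are
# computable on the compact synthetic photoautotroph; stoichiometries are
# balanced for C, N, P and S against the formulae declared in
# new_metabolites.  Gene labels follow the usual engineering literature
# (kivD, phbB/phbC, cimA, PAL/FDC1, hemA, IspS, valencene synthase, farnesene
# synthase, PAL/CHI/CHS).  Notes: the valencene module is sometimes listed
# with three gene labels but two reactions (synthase isoforms); the styrene
# route is a deep lump through aromatic biosynthesis.
module	product_id	reaction_id	equation	gene_label	ec	new_metabolites
isobutanol	ibol_c	als_kari_dhad	2 pyr_c + nadh_c -> kiv_c + co2_c + nad_c + h2o_c	ilvB,ilvC,ilvD	2.2.1.6	kiv_c=C5H8O3
isobutanol	ibol_c	kivd	kiv_c -> ibal_c + co2_c	kivD	4.1.1.72	ibal_c=C4H8O
isobutanol	ibol_c	adh2	ibal_c + nadh_c -> ibol_c + nad_c	ADH2	1.1.1.1	ibol_c=C4H10O
phb	phb_h	phbab	2 acet_h + nadph_h -> hb_h + nadp_h + h2o_h	phbA,phbB	1.1.1.36	hb_h=C4H8O3
phb	phb_h	phbc	hb_h -> phb_h + h2o_h	phbC	2.3.1.304	phb_h=C4H6O2
citramalate	citmal_h	cima	pyr_h + acet_h -> citmal_h	cimA	2.3.1.182	citmal_h=C5H8O5
methylsuccinate	msucc_h	cima	pyr_h + acet_h -> citmal_h	cimA	2.3.1.182	citmal_h=C5H8O5
methylsuccinate	msucc_h	leucd_er	citmal_h + nadph_h -> msucc_h + nadp_h + h2o_h	leuC,leuD,ER		msucc_h=C5H8O4
styrene	sty_c	pal_fdc1	2 pyr_c + gap_c + 4 nadh_c -> sty_c + co2_c + pi_c + 4 nad_c + 6 h2o_c	PAL,FDC1	4.1.1.102	sty_c=C8H8
aminolevulinate	ala5_c	hema	glu_c + atp_c + nadh_c -> ala5_c + adp_c + pi_c + nad_c	hemA	1.2.1.70	ala5_c=C5H9NO3
isoprene	iprn_h	isps_mep	pyr_h + gap_h + 2 nadph_h + atp_h -> iprn_h + co2_h + adp_h + 2 pi_h + 2 nadp_h + 2 h2o_h	IspS,IspG,IspH	4.2.3.27	iprn_h=C5H8
valencene	valc_h	valcs	3 pyr_h + 3 gap_h + 6 nadph_h + 3 atp_h -> valc_h + 3 co2_h + 3 adp_h + 6 pi_h + 6 nadp_h + 6 h2o_h	Valcs,Vals	4.2.3.73	valc_h=C15H24
farnesene	farn_h	afs	3 pyr_h + 3 gap_h + 6 nadph_h + 3 atp_h -> farn_h + 3 co2_h + 3 adp_h + 6 pi_h + 6 nadp_h + 6 h2o_h	afs	4.2.3.24	farn_h=C15H24
naringenin	nar_c	pal_chi_chs	3 pyr_c + 2 gap_c + 2 nadh_c -> nar_c + 2 pi_c + 2 nad_c + 8 h2o_c	PAL,CHI,CHS-A	2.3.1.74	nar_c=C15H12O5
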