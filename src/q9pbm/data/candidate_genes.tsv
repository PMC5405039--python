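# Candidate OsSMF1 target genes: RiceArrayNet co-expression r-values and the
# annotated binding-motif sites (bp upstream of the translation start, 5'-most
# base, position 1 adjacent to the ATG) in their 1-kb promoters.
# Notes on transcription of the published catalogue:
#  - the OsSMF1 self-row is recorded with r = 1.00 (self-correlation); its ACGT
#    motif is reported without a mappable promoter position and is therefore
#    left unplanted in synthetic promoters (acgt_pos empty, acgt_seq kept);
#  - Os03g0179700 prints r = 0.54, marginally below the 0.55 selection
#    threshold; kept as printed.
gene_id	r	gcn4_pos	gcn4_seq	acgt_pos	acgt_seq	atga_pos	atga_seq	description
Os01g0762500	0.63	889	tgagtca					GluA-1
Os10g0400200	0.56	897	tgagtca					GluA-2
Os01g0898500	0.64	773	tgagtca					Patatin-like protein 2 (PAT)
Os06g0133000	0.55	185	tgagtca					Granule-bound starch synthase I, chloroplast precursor (GBSS)
Os03g0168500	0.63	496	tgagtca					Endosperm-specific gene 44 (OsEnS44)
Os03g0712800	0.63	200	tgagtca					Glutamine synthetase root isozyme 2
Os01g0393400	0.62	572	tgagtca					MDR-like ABC transporter
Os03g0799600	0.59	702	tgagtca					ES43-like protein
Os04g0437000	0.58	512	tgagtca					No apical meristem (NAM) domain-containing protein (ONAC79)
Os02g0459400	0.55	272	tgagtca					Conserved hypothetical protein
Os03g0179700	0.54	932	tgagtca					Protein of unknown function DUF567 family protein
Os03g0427300	0.66	898	tgagtca	381	ccacgtc			GluA-3
Os05g0415400	0.55	850	tgagtca	352	ccacgtg			No apical meristem (NAM) domain-containing protein (ONAC024)
Os04g0528000	0.66	716	tgagtca	366	ccacgtg			Protein of unknown function DUF789 family protein
Os02g0268100	0.59	832	tgagtca			171	ggatgac	GluB-5
Os02g0268300	0.57	818	tgagtca			185	ggatgac	GluB-4
Os09g0520400	0.63	715	tgagtca			744	ggatgac	OsbZIP76
Os02g0249500	0.61	105	tgagtca			802	ggatgac	Hypothetical protein
Os05g0499100	0.55			436	ccacgtc			26-kDa globulin (alpha-globulin)
Os07g0182000	1.00				ccacgtc			OsSMF1
Os11g0582400	0.56			100	ccacgtc			Endosperm-specific protein (OsEnS146)
Os01g0393100	0.60			257	ccacgtc			No apical meristem (NAM) domain-containing protein (ONAC026)
Os05g0569400	0.63			650	ccacgtg			Galactose mutarotase-like domain-containing protein
Os01g0133400	0.61			381	ccacgtg			Hexose transporter (fragment)
Os02g0694100	0.59			534	ccacgtc			Cyclin-like F-box domain-containing protein
Os03g0598700	0.59			32	ccacgtc			Zn-finger, RING domain-containing protein
Os05g0404700	0.59			342	ccacgtc			Methyl-CpG-binding protein (MBD1)
Os11g0701100	0.59			832	ccacgtg			Xylanase inhibitor protein 2
Os01g0585100	0.58			966	ccacgtc			Conserved hypothetical protein
Os06g0141400	0.57			10	ccacgtc			Early nodulin
Os05g0557600	0.57			226	ccacgtc			Ubiquitin-conjugating enzyme domain-containing protein
Os04g0508500	0.56			397	ccacgtc			Snapdragon myb protein 305 homolog
Os05g0491400	0.56			196	ccacgtc			LRR protein
Os01g0517800	0.56			862	ccacgtg			PLATZ transcription factor
Os04g0629300	0.55			263	ccacgtc			SNF2-related domain-containing protein
Os10g0138600	0.69			240	ccacgtc	158	ggatgac	Cyclin-like F-box domain-containing protein
Os12g0151000	0.69			426	ccacgtg	233	ggatgac	Purple acid phosphatase
Os02g0252400	0.66					737	ggatgac	Rice prolamin box-binding factor (RPBF)
Os07g0668600	0.65					360	ggatgac	Zinc finger, CCCH-type domain-containing protein (OsGZF1)
Os04g0677400	0.66					975	ggatgac	Conserved hypothetical protein
Os07g0457400	0.62					764	ggatgac	Conserved hypothetical protein
Os03g0766200	0.61					770	ggatgac	Bifunctional inhibitor/plant lipid transfer protein/seed storage domain-containing protein
Os07g0485100	0.60					589	ggatgac	Nitrilase/cyanide hydratase and apolipoprotein N-acyltransferase domain-containing protein
Os07g0603600	0.56					237	ggatgac	Alpha/beta hydrolase family protein
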