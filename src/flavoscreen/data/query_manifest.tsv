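accession	query_id	enzyme_name	pathway_id	role	evalue_class	canonical
KEF29323.1	BpGluA	Beta-glucosidase BpGluA	o_deglycosylation	BpGluA	long	1
KEF27912.1	BpGluB	Beta-glucosidase BpGluB	o_deglycosylation	BpGluB	long	1
KEF28010.1	BpGluD	Beta-glucosidase BpGluD	o_deglycosylation	BpGluD	long	1
KEF28001.1	BpGluE	Beta-glucosidase BpGluE	o_deglycosylation	BpGluE	long	1
AFS33105.1	Bbg572	Beta-glucosidase Bbg572	o_deglycosylation	Bbg572	long	1
AAO76887.1	BtGlu	Beta-glucosidase BtGlu	o_deglycosylation	BtGlu	long	1
AGS77942.1	BdR	Alpha-L-rhamnosidase BdR	derhamnosylation	BdR	long	1
AHJ22585.1	BbR	Alpha-L-rhamnosidase BbR	derhamnosylation	BbR	long	1
WP_011107561	BtR	Alpha-L-rhamnosidase BtR	derhamnosylation	BtR	long	1
QBM20340.1	MGR1	Alpha-L-rhamnosidase HFM-RhaA (MGR1)	derhamnosylation	MGR1	long	1
QBM20341.1	MGR2	Alpha-L-rhamnosidase HFM-RhaB (MGR2)	derhamnosylation	MGR2	long	1
QBM20342.1	MGR3	Alpha-L-rhamnosidase HFM-RhaC (MGR3)	derhamnosylation	MGR3	long	1
CCC80440.1	LpR1	Alpha-L-rhamnosidase LpR1	derhamnosylation	LpR1	long	1
CCC80442.1	LpR2	Alpha-L-rhamnosidase LpR2	derhamnosylation	LpR2	long	1
AAV43293.1	LaR	Alpha-L-rhamnosidase LaR	derhamnosylation	LaR	long	1
EUA80835.1	Phy_Ma	Phloretin hydrolase (Mycobacteroides abscessus)	phy	Phy_Ma	short	1
AAQ12341.1	Phy_Er	Phloretin hydrolase (Eubacterium ramulus)	phy	Phy_Er	short	1
AKC35075.1	DfgC_Cs	DfgC 7-O-deglycosylase subunit	dfgCD	dfgC	short	1
AKC35076.1	DfgD_Cs	DfgD 7-O-deglycosylase subunit	dfgCD	dfgD	short	1
EIM58373.1	DfgA_Ec	DfgA C-deglycosylation subunit	c_deglycosylation_dfg	dfgA	c_degly	1
EIM58372.1	DfgB_Ec	DfgB C-deglycosylation subunit	c_deglycosylation_dfg	dfgB	c_degly	1
EIM58371.1	DfgC_Ec	DfgC C-deglycosylation subunit	c_deglycosylation_dfg	dfgC	c_degly	1
EIM58370.1	DfgD_Ec	DfgD C-deglycosylation subunit	c_deglycosylation_dfg	dfgD	c_degly	1
EIM58369.1	DfgE_Ec	DfgE C-deglycosylation subunit	c_deglycosylation_dfg	dfgE	c_degly	1
BBG22493.1	DgpA	DgpA oxidoreductase	c_deglycosylation_dgp	dgpA	c_degly	1
BBG22494.1	DgpB	DgpB C-glycoside deglycosylase subunit	c_deglycosylation_dgp	dgpB	c_degly	1
BBG22495.1	DgpC	DgpC C-glycoside deglycosylase subunit	c_deglycosylation_dgp	dgpC	c_degly	1
ANU40626.1	Flr_Fp	Flavone/flavonol reductase (Flavonifractor plautii)	flr	Flr_Fp	short	1
ADK16070.1	Flr_Cl	Flavone/flavonol reductase (Clostridium ljungdahlii)	flr	Flr_Cl	short	1
AGS82961.1	Fcr_Er	Flavanone/flavanonol-cleaving reductase (Eubacterium ramulus)	fcr	Fcr_Er	long	1
WP_154024723.1	Fcr_Fp	Flavanone/flavanonol-cleaving reductase (Flavonifractor plautii)	fcr	Fcr_Fp	long	1
AIS36173.1	CHI_Er	Chalcone isomerase (Eubacterium ramulus)	chi	CHI_Er	short	1
EHM54434.1	CHI_Fp	Chalcone isomerase (Flavonifractor plautii)	chi	CHI_Fp	short	1
AFV15450.1	TDR_Si	Tetrahydrodaidzein reductase (Slackia isoflavoniconvertens)	daidzein_equol	tdr	short	1
AFV15451.1	DDR_Si	Dihydrodaidzein reductase (Slackia isoflavoniconvertens)	daidzein_equol	ddr	short	1
AFV15453.1	DZR_Si	Daidzein reductase (Slackia isoflavoniconvertens)	daidzein_equol	dzr	short	1
BAM25050.1	Rac_Lg	Dihydrodaidzein racemase (Lactococcus garvieae)	daidzein_equol	dhd_racemase	short	1
BAL46928.1	TDR_Sn	Tetrahydrodaidzein reductase (Slackia sp. NATTS)	daidzein_equol	tdr	short	0
BAL46929.1	DDR_Sn	Dihydrodaidzein reductase (Slackia sp. NATTS)	daidzein_equol	ddr	short	0
BAL46930.1	DZR_Sn	Daidzein reductase (Slackia sp. NATTS)	daidzein_equol	dzr	short	0
BAJ72744.1	TDR_Lg	Tetrahydrodaidzein reductase (Lactococcus garvieae)	daidzein_equol	tdr	short	0
BAJ72745.1	DDR_Lg	Dihydrodaidzein reductase (Lactococcus garvieae)	daidzein_equol	ddr	short	0
BAJ22678.1	DZR_Lg	Daidzein reductase (Lactococcus garvieae)	daidzein_equol	dzr	short	0
WP_013979960.1	TDR_Ey	Tetrahydrodaidzein reductase (Eggerthella sp. YY7918)	daidzein_equol	tdr	short	0
WP_013979959.1	DDR_Ey	Dihydrodaidzein reductase (Eggerthella sp. YY7918)	daidzein_equol	ddr	short	0
WP_013979957.1	DZR_Ey	Daidzein reductase (Eggerthella sp. YY7918)	daidzein_equol	dzr	short	0
ANI69959.1	AE_El	O-demethylase activating enzyme	o_demethylation	AE	short	1
ANI69960.1	MT1_El	O-demethylase methyltransferase 1	o_demethylation	MT1	short	1
ANI69961.1	CP_El	O-demethylase corrinoid protein	o_demethylation	CP	short	1
ANI69962.1	MT2_El	O-demethylase methyltransferase 2	o_demethylation	MT2	short	1
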