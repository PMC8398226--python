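species	modification_class	flavonoid_classes	prevalence_reported	note
Bacteroides ovatus	O-deglycosylation	Flavonols	3.1
Bacteroides uniformis	O-deglycosylation	Flavonols, flavanones	18.5
Bacteroides thetaiotaomicron	O-deglycosylation	Isoflavones	1.9
Bifidobacterium adolescentis	O-deglycosylation	Flavanones, isoflavones	7.4
Bifidobacterium angulatum	O-deglycosylation	Isoflavones	0.3
Bifidobacterium animalis	O-deglycosylation	Anthocyanidins, isoflavones	0.3
Bifidobacterium bifidum	O-deglycosylation	Flavanones, isoflavones	3.3
Bifidobacterium breve	O-deglycosylation	Flavonols, isoflavones, flavanones	1.5
Bifidobacterium catenulatum	O-deglycosylation	Flavonols, isoflavones, flavanones	0.8
Bifidobacterium dentium	O-deglycosylation	Flavonols, flavanones	0.3
Bifidobacterium infantis	O-deglycosylation	Flavonols, isoflavones, flavanones	8.4
Bifidobacterium longum	O-deglycosylation	Isoflavones	0	classified as Bi. infantis in GTDB
Bifidobacterium pseudocatenulatum	O-deglycosylation	Flavonols, flavanones	3.5
Bifidobacterium pseudolongum	O-deglycosylation	Isoflavones	<0.1
Blautia producta	O-deglycosylation	Flavonols, flavones, flavanones, isoflavones	<0.1	provisional 16S assignment: strain MRG-PMF1, 99% identity
Catenibacillus scindens	O-deglycosylation	Flavones, isoflavones	n.d.	no sequenced genome in GTDB release 89
Enterobacter cloacae	O-deglycosylation	Flavanones	0.1
Enterococcus avium	O-deglycosylation	Flavonols	0.1
Enterococcus casseliflavus	O-deglycosylation	Flavonols	<0.1
Enterococcus faecalis	O-deglycosylation	Flavanones	2.9
Eubacterium cellulosolvens	O-deglycosylation	Flavones, isoflavones	0
Eubacterium ramulus	O-deglycosylation	Flavonols, flavones, dihydrochalcones, isoflavones	0.5
Escherichia coli	O-deglycosylation	Isoflavones	n.d.	provisional 16S assignment: strain HGH21, 99% identity (MIDI)
Escherichia fergusonii	O-deglycosylation	Flavones	<0.1	originally Escherichia sp. 4
Parabacteroides distasonis	O-deglycosylation	Flavonols, flavanones	14.5
Lactobacillus acidophilus	O-deglycosylation	Flavanones	<0.1
Lactobacillus buchneri	O-deglycosylation	Flavanones	<0.1
Lactobacillus casei	O-deglycosylation	Flavanones, anthocyanidins	0
Lactobacillus leichmanii	O-deglycosylation	Flavanones	n.d.	no sequenced genome in GTDB release 89
Lactobacillus plantarum	O-deglycosylation	Flavanones, anthocyanidins	0.2
Lactococcus lactis	O-deglycosylation	Flavonols, isoflavones, flavanones	0.2
Lactococcus paracasei	O-deglycosylation	Isoflavones, flavonols	0.2
Eubacterium cellulosolvens	C-deglycosylation	Flavones, isoflavones	0
Dorea longicatena	C-deglycosylation	Isoflavones	n.d. (2.9)	provisional 16S assignment: strain PUE (1346 nt), 98% identity
Catenibacillus scindens	C-deglycosylation	Flavones, isoflavones	n.d.	no sequenced genome in GTDB release 89
Enterococcus casseliflavus	C-deglycosylation	Flavones	<0.1	provisional 16S assignment: sp. 45, 99% identity
Enterococcus faecium	C-deglycosylation	Isoflavones	1.8	provisional 16S assignment: strain MRG-IFC-2, 99% identity
Lactococcus lactis	C-deglycosylation	Isoflavones	0.2	provisional 16S assignment: strain MRG-IFC-1, 99% identity
Flavonifractor plautii	C-ring_cleavage	Flavonols/flavanonols, flavones/flavanones	2.1	formerly Clostridium orbiscindens
Catenibacillus scindens	C-ring_cleavage	Flavones	n.d.	no sequenced genome in GTDB release 89
Eubacterium ramulus	C-ring_cleavage	Flavonols/flavanonols, flavones/flavanones, isoflavones	0.5	combined value from two GTDB phylogroups
Clostridium butyricum	C-ring_cleavage	Flavanones	0.3
Lactobacillus plantarum	C-ring_cleavage	Flavan-3-ols	0.2
Eubacterium_I sp000270305	C-ring_cleavage	Isoflavones	n.d.	originally strain SY8519
Adlercreutzia equolifaciens	C-ring_cleavage	Flavan-3-ols	0.8
Eggerthella lenta	C-ring_cleavage	Flavanonols (SDG-2), flavan-3-ols	0.9
Enterococcus faecium	C-ring_cleavage	Isoflavones	1.8
Bifidobacterium animalis	Reduction	Isoflavones	0.3
Bifidobacterium longum	Reduction	Isoflavones	0	classified as Bi. infantis in GTDB
Bifidobacterium pseudolongum	Reduction	Isoflavones	<0.1
Adlercreutzia equolifaciens	Reduction	Isoflavones	0.8
Lactococcus garvieae	Reduction	Isoflavones	<0.1
Slackia sp. NATTS	Reduction	Isoflavones	n.d.	no sequenced genome in GTDB release 89
Slackia isoflavoniconvertens	Reduction	Isoflavones	n.d.	no GTDB assignment; MAG cluster GUT_GENOME145587 matches at 95% ANI
Lactobacillus rhamnosus	Reduction	Isoflavones	0.4
Enterococcus faecalis	Reduction	Isoflavones	2.9
Enterococcus faecium	Reduction	Isoflavones	1.8
Escherichia fergusonii	Dehydroxylation	Flavones	<0.1
Adlercreutzia equolifaciens	Dehydroxylation	Flavan-3-ols	0.8
Eggerthella lenta	Dehydroxylation	Flavan-3-ols	0.9	provisional 16S assignment: SDG-2, 99% identity
Blautia producta	O-demethylation	Flavonols, flavones, flavanones, isoflavones	<0.1	provisional 16S assignment: strain MRG-PMF1, 99% identity
Eubacterium limosum	O-demethylation	Isoflavones, flavanones	<0.1
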