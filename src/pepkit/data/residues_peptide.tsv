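# Peptide residue database seed.
# formula: chain-incorporated (dehydrated) composition; termini supply end-group atoms.
# ionizable: key into the pKa set ('-' = side chain carries no charge term).
# chromophore: Trp | Tyr | Cys contribution to epsilon(280 nm).
# protectable: comma list of protecting-group names licensed on this residue.
# version: 1
code	name	formula	canonical	ionizable	chromophore	protectable
G	glycine	C2H3NO	1	-	-	-
A	alanine	C3H5NO	1	-	-	-
S	serine	C3H5NO2	1	-	-	tBu
P	proline	C5H7NO	1	-	-	-
V	valine	C5H9NO	1	-	-	-
T	threonine	C4H7NO2	1	-	-	tBu
C	cysteine	C3H5NOS	1	C	Cys	Trt
L	leucine	C6H11NO	1	-	-	-
I	isoleucine	C6H11NO	1	-	-	-
N	asparagine	C4H6N2O2	1	-	-	Trt
D	aspartic acid	C4H5NO3	1	D	-	tBu
Q	glutamine	C5H8N2O2	1	-	-	Trt
K	lysine	C6H12N2O	1	K	-	Boc
E	glutamic acid	C5H7NO3	1	E	-	tBu
M	methionine	C5H9NOS	1	-	-	-
H	histidine	C6H7N3O	1	H	-	Trt
F	phenylalanine	C9H9NO	1	-	-	-
R	arginine	C6H12N4O	1	R	-	Pbf
Y	tyrosine	C9H9NO2	1	Y	Tyr	tBu
W	tryptophan	C11H10N2O	1	-	Trp	Boc
pS	phosphoserine	C3H6NO5P	0	-	-	-
pT	phosphothreonine	C4H8NO5P	0	-	-	-
pY	phosphotyrosine	C9H10NO5P	0	-	-	-
Hyp	4-hydroxyproline	C5H7NO2	0	-	-	-
Nle	norleucine	C6H11NO	0	-	-	-
Orn	ornithine	C5H10N2O	0	-	-	-
Cit	citrulline	C6H11N3O2	0	-	-	-
Aib	2-aminoisobutyric acid	C4H7NO	0	-	-	-
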