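token	smiles	source
S-PHOS	N[C@@H](COP(=O)(O)O)C(=O)O	O-phosphoserine
T-PHOS	C[C@@H](OP(=O)(O)O)[C@H](N)C(=O)O	O-phosphothreonine
Y-PHOS	N[C@@H](Cc1ccc(OP(=O)(O)O)cc1)C(=O)O	O-phosphotyrosine
R-CIT	N[C@@H](CCCNC(N)=O)C(=O)O	L-citrulline (deiminated arginine)
P-HYP	O=C(O)[C@@H]1C[C@H](O)CN1	trans-4-hydroxyproline
K-ME1	CNCCCC[C@H](N)C(=O)O	N6-methyllysine
K-ME2	CN(C)CCCC[C@H](N)C(=O)O	N6,N6-dimethyllysine
K-ME3	C[N+](C)(C)CCCC[C@H](N)C(=O)O	N6,N6,N6-trimethyllysine
K-AC	CC(=O)NCCCC[C@H](N)C(=O)O	N6-acetyllysine
K-FORM	O=CNCCCC[C@H](N)C(=O)O	N6-formyllysine
Y-NO2	N[C@@H](Cc1ccc(O)c(c1)[N+](=O)[O-])C(=O)O	3-nitrotyrosine
Y-SULF	N[C@@H](Cc1ccc(OS(=O)(=O)O)cc1)C(=O)O	O-sulfotyrosine
R-ME1	CNC(=N)NCCC[C@H](N)C(=O)O	omega-N-methylarginine
R-ME2A	CN(C)C(=N)NCCC[C@H](N)C(=O)O	asymmetric dimethylarginine
R-ME2S	CNC(=NC)NCCC[C@H](N)C(=O)O	symmetric dimethylarginine
C-CAM	NC(=O)CSC[C@H](N)C(=O)O	S-carbamidomethylcysteine
C-SO3H	O=S(=O)(O)C[C@H](N)C(=O)O	cysteic acid (cysteine sulfonic acid)
M-OX	CS(=O)CC[C@H](N)C(=O)O	methionine sulfoxide
E-GLA	OC(=O)C(CC[C@H](N)C(=O)O)C(=O)O	gamma-carboxyglutamate
Q-PCA	O=C1CC[C@H](N1)C(=O)O	pyroglutamate (pyrrolidone carboxylate)
W-OH	N[C@@H](Cc1c[nH]c2ccc(O)cc12)C(=O)O	5-hydroxytryptophan
W-KYN	N[C@@H](CC(=O)c1ccccc1N)C(=O)O	L-kynurenine (oxidized tryptophan)
H-ME1	Cn1cncc1C[C@H](N)C(=O)O	N1-methylhistidine
N-DEAM	N[C@@H](CC(=O)O)C(=O)O	deamidated asparagine (aspartate form)
S-AC	CC(=O)OC[C@H](N)C(=O)O	O-acetylserine
T-AC	CC(=O)O[C@@H](C)[C@H](N)C(=O)O	O-acetylthreonine
A-AIB	CC(C)(N)C(=O)O	2-aminoisobutyrate (alpha-methylalanine)
G-SAR	CNCC(=O)O	sarcosine (N-methylglycine)
F-AME	CC(N)(Cc1ccccc1)C(=O)O	alpha-methylphenylalanine
L-NLE	CCCC[C@H](N)C(=O)O	L-norleucine
V-NVA	CCC[C@H](N)C(=O)O	L-norvaline
I-ALO	CC[C@@H](C)[C@@H](N)C(=O)O	L-allo-isoleucine
D-OME	COC(=O)C[C@H](N)C(=O)O	aspartate beta-methyl ester
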