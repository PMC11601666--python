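token	smiles	source
A	C[C@@H](N)C(=O)O	L-alanine, free amino acid
R	N[C@@H](CCCNC(=N)N)C(=O)O	L-arginine, free amino acid
N	NC(=O)C[C@H](N)C(=O)O	L-asparagine, free amino acid
D	N[C@@H](CC(=O)O)C(=O)O	L-aspartate, free amino acid
C	N[C@@H](CS)C(=O)O	L-cysteine, free amino acid
E	N[C@@H](CCC(=O)O)C(=O)O	L-glutamate, free amino acid
Q	NC(=O)CC[C@H](N)C(=O)O	L-glutamine, free amino acid
G	NCC(=O)O	glycine, free amino acid
H	N[C@@H](Cc1c[nH]cn1)C(=O)O	L-histidine, free amino acid
I	CC[C@H](C)[C@@H](N)C(=O)O	L-isoleucine, free amino acid
L	CC(C)C[C@H](N)C(=O)O	L-leucine, free amino acid
K	N[C@@H](CCCCN)C(=O)O	L-lysine, free amino acid
M	CSCC[C@H](N)C(=O)O	L-methionine, free amino acid
F	N[C@@H](Cc1ccccc1)C(=O)O	L-phenylalanine, free amino acid
P	O=C(O)[C@@H]1CCCN1	L-proline, free amino acid
S	N[C@@H](CO)C(=O)O	L-serine, free amino acid
T	C[C@@H](O)[C@H](N)C(=O)O	L-threonine, free amino acid
W	N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O	L-tryptophan, free amino acid
Y	N[C@@H](Cc1ccc(O)cc1)C(=O)O	L-tyrosine, free amino acid
V	CC(C)[C@H](N)C(=O)O	L-valine, free amino acid
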