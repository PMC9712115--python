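codon	aa	fraction
TTT	F	0.57
TTC	F	0.43
TTA	L	0.13
TTG	L	0.13
CTT	L	0.10
CTC	L	0.10
CTA	L	0.04
CTG	L	0.50
ATT	I	0.51
ATC	I	0.42
ATA	I	0.07
ATG	M	1.00
GTT	V	0.26
GTC	V	0.22
GTA	V	0.15
GTG	V	0.37
TCT	S	0.15
TCC	S	0.15
TCA	S	0.12
TCG	S	0.15
AGT	S	0.15
AGC	S	0.28
CCT	P	0.16
CCC	P	0.12
CCA	P	0.19
CCG	P	0.53
ACT	T	0.17
ACC	T	0.43
ACA	T	0.13
ACG	T	0.27
GCT	A	0.16
GCC	A	0.27
GCA	A	0.21
GCG	A	0.36
TAT	Y	0.57
TAC	Y	0.43
CAT	H	0.57
CAC	H	0.43
CAA	Q	0.35
CAG	Q	0.65
AAT	N	0.45
AAC	N	0.55
AAA	K	0.77
AAG	K	0.23
GAT	D	0.63
GAC	D	0.37
GAA	E	0.69
GAG	E	0.31
TGT	C	0.45
TGC	C	0.55
TGG	W	1.00
CGT	R	0.38
CGC	R	0.40
CGA	R	0.06
CGG	R	0.10
AGA	R	0.04
AGG	R	0.02
GGT	G	0.34
GGC	G	0.40
GGA	G	0.11
GGG	G	0.15
TAA	*	0.64
TAG	*	0.07
TGA	*	0.29
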