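residue	shift_da	name
M	15.99491	Oxidation
W	15.99491	Oxidation
H	15.99491	Oxidation
C	15.99491	Oxidation
Y	15.99491	Oxidation
F	15.99491	Oxidation
P	15.99491	Oxidation
K	15.99491	Oxidation
R	15.99491	Oxidation
N	0.98402	Deamidation
Q	0.98402	Deamidation
S	79.96633	Phosphorylation
T	79.96633	Phosphorylation
Y	79.96633	Phosphorylation
K	42.01057	Acetylation
S	42.01057	Acetylation
T	42.01057	Acetylation
C	57.02146	Carbamidomethyl
K	57.02146	Carbamidomethyl
H	57.02146	Carbamidomethyl
K	14.01565	Methylation
R	14.01565	Methylation
H	14.01565	Methylation
C	14.01565	Methylation
N	14.01565	Methylation
Q	14.01565	Methylation
D	14.01565	Methylation
E	14.01565	Methylation
K	28.03130	Dimethylation
R	28.03130	Dimethylation
K	42.04695	Trimethylation
R	42.04695	Trimethylation
M	31.98983	Dioxidation
W	31.98983	Dioxidation
C	31.98983	Dioxidation
K	27.99491	Formylation
S	27.99491	Formylation
T	27.99491	Formylation
C	47.98474	Trioxidation
S	27.01090	Carbamylation
K	43.00581	Carbamylation
R	43.00581	Carbamylation
C	45.98772	Persulfide
M	-48.00337	Dethiomethyl
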