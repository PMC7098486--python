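name	delta_mass	composition	residues
TMT	229.163	C8H20N1O2C[13]4N[15]1	K,N-term
Carbamidomethyl	57.021	C2H3N1O1	C
Oxidation	15.995	O1	M
Phospho	79.966	H1P1O3	S,T
Deamidation	0.984	H-1N-1O1	N,Q
GlyGly	114.0429	C4H6N2O2	K
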