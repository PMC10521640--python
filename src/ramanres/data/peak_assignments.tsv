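raman_shift	intensity	vibrational_mode	component
497	Weak	s (S-S)	DNA
599	Mid	v (N-H)	Cytosine
725	Mid	bv (N-H)	Adenine
810	Mid	v (Ca-O-P-O-Cb)	Phosphodiester
876	Weak	v (O-O)	Lactate
890	Weak	d (C-O-H)	Glucose
936	Strong	s (Ca-Cb)	Polysaccharides
986	Strong	v (Ca-Cb or C-O)	Ribose
1014	Mid	v (pyr half-ring)	Glucose
1125	Weak	v (Cb-methyl)	Protein
1130	Mid	s (C-N)	D-mannose
1156	Weak	v (pyr half-ring) sym	Glucose
1210	Weak	bv (N-H), s (C-H)	Amide
1328	Strong	t (CH2)	DNA/RNA
1447	Strong	bv (C-H)	Collagen
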