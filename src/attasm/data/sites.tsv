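# attasm site library, version 1.
# Columns: system, variant, core, B_left, B_right, P_left, P_right.
# Cores of the lambda-1, lambda-2 and HK022 attachment sites are the
# published attB core sequences; the Phi80 core and ALL arm sequences are
# SYNTHETIC placeholders (deterministic, frozen). The recombination algebra
# is arm-agnostic; replace arms/cores via a user site library file to model
# wild-type sites at base-pair fidelity.
# attL = B_left|core|P_right ; attR = P_left|core|B_right.
lambda	1	ACAAGTTTGTACAAAAAAGCAGGCT	CGCACT	ACGCTA	TTGCAGGTTCCAGACATC	AAACTTCAGGAGACAGAC
lambda	2	ACCACTTTGTACAAGAAAGCTGGGT	GCCGAA	TGAGTT	CGGGTATTCAGGGGCAGA	CCTCCAACTTCATGATGC
HK022	-	AACCTTTTTCACCTAAAGTGCACC	CCTTTA	GCCCAG	ATTGTGAAGCCTCTTACG	TAGCTGGCTAATCCATGG
Phi80	-	AGTATAGCGATCATATAGCGGTGT	GCCCTG	TTAATT	AGCTCAGTTTCCACCTTT	ACCCGCTCCCCCGTAATT
# Symmetric systems: columns core, left, right (both orientations identical
# site structure; sequences are the canonical published sites).
P1-lox	-	ATGTATGC	ATAACTTCGTATA	TATACGAAGTTAT	-	-
FLP-frt	-	TCTAGAAA	GAAGTTCCTATTC	GAATAGGAACTTC	-	-
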