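# Mass-shifting modifications considered during peak assignment.
# gain/loss: formula strings applied to the whole species ('-' = nothing).
# Metals follow the salt-form convention: the cation replaces one proton.
# sites: '*' = unrestricted; otherwise comma list of licensing residue codes,
# 'N-terminus' licenses one occurrence on a free (unmodified) N-terminus.
# version: 1
name	kind	gain	loss	sites	max_per_site
Na	metal	Na	H	*	1
K	metal	K	H	*	1
Pbf	protecting_group	C13H16O3S	-	R	1
Boc	protecting_group	C5H8O2	-	K,W,N-terminus	1
tBu	protecting_group	C4H8	-	S,T,Y,D,E	1
Trt	protecting_group	C19H14	-	C,H,N,Q	1
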