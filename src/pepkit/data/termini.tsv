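# Predefined termini. formula = atoms added to the bare chain end.
# 'unmodified' + 'acid' together reconstitute the free peptide (chain + H2O).
# version: 1
name	end	formula
unmodified	N	H
acetyl	N	C2H3O
formyl	N	CHO
boc	N	C5H9O2
acid	C	HO
amide	C	H2N
methyl ester	C	CH3O
ethyl 3-mercaptopropionate thioester	C	C5H9O2S
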