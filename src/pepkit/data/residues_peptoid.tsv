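# Peptoid (N-substituted glycine) building-block database seed.
# formula: chain-incorporated (dehydrated) composition.
# version: 1
code	name	formula
Nme	sarcosine (N-methylglycine)	C3H5NO
Nab	N-(4-aminobutyl)glycine	C6H12N2O
Nae	N-(2-aminoethyl)glycine	C4H8N2O
Nlys	N-(4-aminobutyl)glycine	C6H12N2O
Npe	N-(2-phenylethyl)glycine	C10H11NO
Nspe	N-((S)-1-phenylethyl)glycine	C10H11NO
Nrpe	N-((R)-1-phenylethyl)glycine	C10H11NO
Npm	N-benzylglycine	C9H9NO
Nib	N-isobutylglycine	C6H11NO
Nbu	N-butylglycine	C6H11NO
Nce	N-(2-carboxyethyl)glycine	C5H7NO3
Nhe	N-(2-hydroxyethyl)glycine	C4H7NO2
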