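# Ionizable-group pKa set (IPC_peptide values, Kozlowski 2016).
# type: acidic groups contribute -1/(1+10^(pKa-pH)), basic +1/(1+10^(pH-pKa)).
# version: 1
group	pka	type
n_term	9.564	basic
c_term	2.383	acidic
C	8.297	acidic
D	3.887	acidic
E	4.317	acidic
H	6.018	basic
K	10.517	basic
R	12.503	basic
Y	10.071	acidic
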