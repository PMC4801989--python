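# Most-abundant-isotope atomic masses in u (AME2020 rounded to 10 decimal digits).
# version: 1
symbol	mass
H	1.0078250319
C	12.0
N	14.0030740052
O	15.9949146221
S	31.97207069
P	30.97376151
Na	22.98976928
K	38.9637064864
F	18.9984031627
Cl	34.968852682
Br	78.9183376
I	126.904473
Se	79.9165218
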