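# pepkit

Offline calculators for peptide and peptoid chemistry:

- **Molecular formula / weight** from sequence strings (monoisotopic,
  most-abundant-isotope masses), with customizable termini.
- **Automatic mass-spectral peak assignment**: singly-charged m/z values are
  matched against deletion sequences, metal adducts (Na/K, salt-form
  convention) and unremoved protecting groups (Pbf, Boc, tBu, Trt) by an
  iterative-deepening search with length-dependent iteration caps.
- **Isoelectric point** (Henderson–Hasselbalch net charge, bisection root
  finding) and **molar extinction coefficient at 280 nm** (Trp/Tyr/cystine
  terms, oxidized and reduced values).
- **β-strand contiguity profiles** via sliding-window Chou–Fasman propensity
  ratios (window sizes 4–20, cutoff 1.2).
- **ChemDraw CDXML export** of all-atom structures for both polymer classes
  (peptoid side chains on the backbone nitrogen).

Peptide input uses single-letter codes with nonstandard residues in
parentheses (`AC(pS)G`); peptoid input uses dash-separated codes with nested
repeat groups (`((Nme)2-Npe)3`). Sequences are capped at 150 residues after
repeat expansion. Constant tables (element masses, residues, pKa set,
Chou–Fasman propensities, modifications, termini) ship as versioned TSV
files under `src/pepkit/data/` and can be overridden per run.

## CLI

```sh
# full peptide report (JSON) with peak assignment and structure export
pepkit peptide --seq "AC(pS)GW" --peaks "408.1, 337.1" --cdxml out.cdxml

# thioester-capped peptide, assignment table as TSV
pepkit peptide --seq "SYFPKFPKR" \
    --cterm "ethyl 3-mercaptopropionate thioester" \
    --peaks "1197.8 1063.7" --out tsv

# peptoid with repeat grammar
pepkit peptoid --seq "(Nme-Npe)3" --peaks 800.5

# seeded synthetic spectra with a ground-truth ledger
pepkit fixtures --seed 7 --n-spectra 5
```

Termini are chosen by predefined name (`unmodified`, `acetyl`, `formyl`,
`boc`; `acid`, `amide`, `methyl ester`, `ethyl 3-mercaptopropionate
thioester`) or by a custom formula string giving the atoms added to the bare
chain end (e.g. `--nterm C2H3O` for acetyl). Reports print to stdout;
diagnostics go to stderr as a single line with a nonzero exit status.

## Library

```python
import pepkit as pk

seq = pk.parse_peptide("AC(pS)G")
pk.molecular_formula(seq).hill()     # 'C11H20N4O10PS' ... etc.
pk.molecular_weight(seq)
pk.isoelectric_point(seq)
pk.extinction_280(seq)
pk.contiguity_profile(pk.parse_peptide("V" * 12))
pk.assign_peaks(seq, [408.1])
pk.sequence_to_cdxml(seq)
```

New residues can be registered at run time through
`ChemDatabases.residues.register(...)` and are immediately usable by the
parsers and calculators.

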