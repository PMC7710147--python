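# cleavekit

A toolkit for characterizing protease digestion behaviour from peptide-level
data: in-silico digestion with configurable cleavage rules, specificity and
missed-cleavage profiling of identified-peptide lists, cleavage-site
sequence-context statistics, multi-enzyme sequence-coverage and phosphosite
analysis, de novo peptide assembly against a reference, and low-pH disulfide
species mass mapping. A seeded synthetic-data module generates every input
the pipeline consumes, so the full analysis surface is testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `cleavekit.digestion` | FASTA I/O (UniProt-style headers with `a-b` residue-range tokens), cleavage-rule engine, fully- and semi-specific digestion, monoisotopic peptide masses from a bundled versioned constant table |
| `cleavekit.simulate` | Synthetic proteomes, mechanistic per-site cleavage simulation with basophilic context modifiers, terminal-composition peptide sampling (pH presets), phosphosite tables, de novo reads, nonreduced disulfide digests with ppm noise |
| `cleavekit.specificity` | Terminal residue frequencies, enzyme-specificity fraction, missed-cleavage distributions, replicate averaging |
| `cleavekit.context` | P1/P1'-aligned context windows for cleaved vs missed sites, positional motif enrichment against a background, cleaved/missed ratios |
| `cleavekit.coverage` | Per-protein coverage masks, multi-enzyme merging, complementarity (Venn-style counts), diagnostic-position coverage, class-I phosphosite filtering, pooled-variance one-tailed t test |
| `cleavekit.denovo` | Score filtering, combinatorial enzyme-set merging, minimal-mismatch alignment with I/L equivalence, per-combination coverage tables |
| `cleavekit.disulfide` | Cysteine peptide enumeration, disulfide-linked species masses (−2H per bond), ppm precursor matching, in-source-reduction triad validation, scrambling flags |
| `cleavekit.cli` | `cleavekit` command-line interface orchestrating all stages |

## CLI

Every subcommand accepts `--config run.json` (defaults overridable by
flags) and writes TSV tables with JSON parameter sidecars. Exit codes:
0 ok, 1 data error, 2 configuration error.

```sh
# digest a FASTA file
cleavekit digest --fasta proteins.fasta --enzyme proalanase --max-missed 4 --out out/

# simulate an identified-peptide list with the pH 1.5 terminal preset
cleavekit simulate --mode terminal --preset pH1_5 --n-peptides 5000 --seed 42 --out out/

# profile it (or simulate + profile in one step by omitting --peptides)
cleavekit profile --peptides out/peptides.tsv --enzyme proalanase --out out/

# cleavage-context motifs, coverage, de novo assembly, disulfide matching
cleavekit motif --fasta proteins.fasta --peptides out/peptides.tsv --out out/
cleavekit coverage --fasta proteins.fasta --peptides out/peptides.tsv --out out/
cleavekit denovo --reads reads.tsv --reference-fasta ref.fasta --min-score 90 --out out/
cleavekit disulfide --fasta chains.fasta --observations obs.tsv --ppm-tol 5 --out out/
```

Bundled enzyme presets: `proalanase` (C-term {P,A}, hydroxyproline-aware),
`trypsin_p`, `trypsin` (classic, no cleavage before proline), `gluc`
({D,E}), `aspn` (N-term {D}), and `pasg` (C-term {P,A,S,G}, a semi-specific
search setting for nonreduced digests — not an enzymology claim).

## Conventions

- All reported coordinates are 1-based inclusive; internal indexing is
  0-based half-open. A header range token (`>sp|X|1663-2318`) sets a
  reporting offset only.
- Residues B/Z/U/O are rejected at parse time; X is allowed in sequences
  but is never a cleavage site and has no defined mass.
- Protein N-/C-termini count as specific termini.
- Masses are monoisotopic, from a bundled 6-decimal table
  (`cleavekit.constants`, versioned); each disulfide bond subtracts
  2 × 1.0078250319 Da.
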