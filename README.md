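# talocus

Detection, copy-number calling, conservation analysis and antitoxin-toxin
base-pairing assessment of chromosomal type I toxin-antitoxin (TA) loci in
bacterial genome assemblies — plus a synthetic pan-genome simulator with
planted ground truth, so the whole pipeline is testable end to end without
downloading any real assemblies.

## What it does

- **`talocus.synthio`** — generates synthetic pan-genomes: random replicons
  with planted TA loci (full, interrupted-by-insertion, antitoxin-only,
  toxin-only, multi-copy, plasmid-borne, absent), point-mutation noise with
  element protection, duplicate strain names, and metadata labels
  (pathotype / geography) with an optional planted copy-number effect.
  Every plant is recorded in a truth TSV.
- **`talocus.align`** — a bespoke seed-and-extend local nucleotide aligner:
  exact word seeding on both strands, ungapped X-drop extension, banded
  affine-gap extension, Karlin-Altschul bit scores and E-values (raw m·n
  search space, no length correction). A full Smith-Waterman implementation
  is included as an independent optimal-alignment oracle, plus a BLAST
  outfmt-6 reader/writer for interoperability.
- **`talocus.loci`** — turns hits into locus calls: genomic clustering,
  spurious-hit filtering (short terminator-region matches, palindromic
  opposite-strand echoes), classification into
  full / interrupted / antitoxin-only / toxin-only / partial, copy-number
  accounting in 0.5 units, bit-score locus typing (O/P/Q), plasmid
  detection from record descriptions, set-logic categorization, and
  duplicate-strain deduplication.
- **`talocus.conserve`** — maps annotated elements (promoter boxes, TF
  boxes, RBS, ORF, ...) through alignments, computes per-element identity
  fractions and variant tables, builds consensus/count matrices with
  per-column information content, translates ORFs and catalogues protein
  variants (e.g. "N2S").
- **`talocus.pairing`** — scores antitoxin→toxin repression potential by
  antisense scanning: repressive iff ≥15 nt of contiguous Watson-Crick
  pairing or a ≥17 nt window with exactly one internal mismatch.
- **`talocus.mcstats`** — Monte Carlo one-way ANOVA (label shuffling) and a
  Monte Carlo Tukey-style pairwise test (max-studentized-difference null),
  with an exhaustive-permutation oracle for small cases.
- **`talocus.cli`** — orchestrates simulate → scan → classify → conserve →
  pair → stats with TSV/JSON outputs and a deterministic run log.

## CLI

```sh
# simulate a pan-genome with planted truth
talocus simulate --n 50 --seed 1 --out sim/

# full pipeline: scan, classify, dedupe, conserve, pair, stats
talocus run --queries sim/queries.fasta --elements sim/elements.tsv \
            --genomes sim/genomes --metadata sim/metadata.tsv \
            --out results/ --seed 1 --iterations 10000

# individual stages
talocus scan ...      # hit table only (BLAST outfmt-6 columns)
talocus classify ...  # locus calls + copy numbers, no stats
talocus stats --copy-table results/copy_number.tsv \
              --value-col copies_ta1 --seed 1 --out stats.json
```

Key outputs under `--out`: `hits.tsv` (outfmt-6, 1-based inclusive
coordinates), `locus_calls.tsv`, `partial_calls.tsv`, `copy_number.tsv`,
`set_categories.tsv`, `element_conservation.tsv`, `consensus_matrices.tsv`,
`protein_variants.tsv`, `pairing.tsv`, `stats.json`, `summary.json`,
`run_log.txt`. Re-running with an identical config reproduces every file
byte for byte.

## Conventions

Coordinates are 0-based half-open everywhere except the outfmt-6 hit table
(1-based inclusive, minus-strand hits with sstart > send, as in BLAST).
Copy units: full or interrupted pair = 1.0, orphan antitoxin or orphan
toxin = 0.5. All randomness flows from explicit seeds; per-assembly RNG
streams are derived as `default_rng([seed, assembly_index])`.
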