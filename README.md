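# hawmap

One-step whole-genome-sequencing + SNP mapping-by-sequencing for
*C. elegans* mutant identification.

## The problem

Forward genetic screens in *C. elegans* yield mutants whose causal lesion is
buried among hundreds of mutagen-induced background variants (EMS leaves
~300 variants per chromosome, ~30 of them in coding sequence). The classic
shortcut is SNP mapping: cross the mutant (a Bristol/N2 derivative) to the
polymorphic Hawaiian isolate CB4856, which differs from Bristol at ~100,000
catalogued SNPs (~1 per kb), and read out which parental haplotypes
co-segregate with the phenotype.

`hawmap` implements — and simulates end to end — the one-step version of
this strategy: pick 20–50 F2 progeny showing the mutant phenotype, pool
their selfed progeny, and whole-genome sequence the pool once. At every
catalogued SNP locus the pileup gives a Hawaiian read ratio

```
HA ratio = hawaiian reads / total reads
```

Unlinked loci segregate freely and sit near 0.5. Because every selected F2
is homozygous Bristol at the causal locus, loci linked to it are depleted
of Hawaiian reads in proportion to their genetic distance *d*: the expected
pool Hawaiian frequency is the recombination fraction *r(d) = d/100* (for
*d* ≤ 50 cM). The mutation-bearing region shows up as an extended stretch
with **no** filtered Hawaiian signal, and the same sequencing run supplies
the candidate variants inside it.

The toolkit provides:

- **genome model** — chromosomes with physical (bp) and genetic (cM,
  center-zero) coordinates tied by piecewise-linear maps, plus a generator
  for synthetic Bristol/Hawaiian SNP catalogs with "falsely annotated"
  (blacklisted) loci;
- **pool simulator** — F1 meioses with one obligate crossover per bivalent,
  phenotype selection of homozygous F2s, pooled allele frequencies, and
  Poisson/binomial read sampling at every catalog locus, plus EMS-like
  background variants and the injected causal stop;
- **snp mapper** — HA ratios, the ≥3-Hawaiian-reads / 0.2–0.6-ratio filter
  (with blacklist), per-chromosome largest-gap interval detection with
  terminal sentinels, mutation-chromosome calling, and scatter exports;
- **variant caller** — MAQ-style calling thresholds (depth ≥ 3, qualities
  ≥ 3, multiplicity ≤ 1, non-reference fraction ≥ 0.8), codon-level
  functional classification, and the protein-changing candidate filter
  restricted to the mapping interval;
- **cli_io** — strict TSV formats with audited `#` headers, YAML run
  configs, and a composable CLI.

## Worked example

```sh
hawmap -v run --seed 1 --outdir demo
```

simulates the default experiment — 50 selected F2 recombinants on the
six-chromosome *C. elegans* genome, causal lesion at X:9,941,000, 20×
coverage — then maps and filters. The log shows the per-stage counts:

```
simulate: 100382 catalog loci, 2191 variant records
filter: passing SNPs per chromosome {'I': 13435, 'II': 11880, 'III': 11695,
                                     'IV': 15007, 'V': 17768, 'X': 4229}
intervals: called X widest gap 9.931 cm on X; runner-up 0.042 cm on II
variants: 1834 called, 65 in interval, 6 protein-changing candidates
```

Every chromosome except X carries ~12–18 thousand passing Hawaiian SNPs
spread evenly; X shows only 4,229 and a huge depleted gap. `summary.json`
records the call:

```json
"called_chromosome": "X",
"interval": {"left_bp": 7709806, "right_bp": 11229019,
             "size_mb": 3.51, "size_cm": 9.93},
"n_candidates": 6
```

The called interval (3.51 Mb between the two flanking passing SNPs) contains
6 protein-changing candidate variants, among them the injected causal stop
at X:9,941,000 — the needle recovered from ~2,000 background variants in a
single simulated sequencing run. Stage outputs (`catalog.tsv`,
`pileup.tsv`, `ratios.tsv`, `intervals.tsv`, `scatter.tsv`,
`candidates.tsv`) are plain TSV and compose through the `simulate`,
`ratios`, `map` and `variants` subcommands.

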