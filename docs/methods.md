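# Methods

## The genetic model

A cross between a mutagenized Bristol (N2) mutant and the Hawaiian (CB4856)
isolate produces F1 heterozygotes; their F2 progeny are phenotype-selected
so that every pooled animal is homozygous Bristol at the causal locus. The
pool is sequenced once, and each of the ~100,000 catalogued Bristol/Hawaiian
SNP loci reports a Hawaiian read ratio. `hawmap` simulates this experiment
generatively and implements the downstream mapping computation exactly as a
bench scientist would run it on a spreadsheet of per-SNP pileups.

### Coordinates

Physical coordinates are 1-based inclusive bp. Genetic coordinates are
centimorgans with the zero near the chromosome center (so left-arm
positions are negative), matching the convention of the *C. elegans*
genetic map. A `GeneticMap` is a strictly monotone piecewise-linear
relation anchored at the chromosome ends; without explicit anchors every
chromosome gets a uniform map spanning [−L/2, +L/2] for genetic length
L = 50 cM. The default genome uses the six *C. elegans* chromosome lengths
(~100.3 Mb total), so a 1/1,000 bp catalog density yields ~100,000 loci.

### Meiosis

One obligate crossover per bivalent, uniform in genetic distance, with the
transmitted chromatid recombinant with probability 1/2 (two of four
chromatids carry the exchange). This is complete crossover interference —
a good approximation for *C. elegans*, where bivalents almost always
resolve a single chiasma — and with 50 cM chromosomes it reproduces the
standard map relation r(d) = d/100 exactly for d ≤ 50 cM (verified by the
gamete-level recovery test, 10,000 gametes, 3 SE). A no-interference
(Poisson crossover) mode is deliberately out of scope.

### Selection and pooling

Selected F2s are drawn by rejection sampling: a genotype is kept iff both
gametes carry Bristol at the causal locus (acceptance probability 1/4, so
the sampler terminates after 4 expected draws per animal). Recessive and
dominant lesions are computationally identical because in both designs only
homozygous F2 animals enter the pool (dominant alleles require an F3
progeny test at the bench; the simulator just records the mode).

Pooling is modeled at the F2 allele level with optional per-animal weights
(default equal, emulating "similar numbers of animals per plate"). The
bench protocol actually pools selfed F3/F4 progeny, but selfing preserves
expected allele frequencies, and with many worms per plate the realized
plate-level frequencies concentrate tightly around those expectations, so
the F2-level model has the same mean structure. This is a documented
simplification; it slightly understates pool-frequency variance.

### Read sampling

Depth at each catalog locus is Poisson(mean_depth), independent across
loci — no GC, mappability or library bias. Each read reports the Hawaiian
base with probability f·(1−e) + (1−f)·e/3 and the Bristol base with
probability (1−f)·(1−e) + f·e/3, where f is the pool Hawaiian frequency
and e the per-base miscall rate (default 10⁻³); a miscall lands on one
specific wrong base with probability e/3, and reads showing neither
catalogued base count only toward total depth. Blacklisted ("falsely
annotated") loci — positions where Bristol stocks actually carry the
annotated Hawaiian base — are sampled with f forced to 1.0, which is how
they present in real Bristol-derived data; the catalog flags ~0.4% of loci
(a few hundred genome-wide).

### Background variants

Per chromosome the mutagen-induced variant count is Poisson(300); classes
are drawn from a fixed categorical distribution calibrated so coding
classes (missense 6%, silent 2.5%, stop 1%, splice donor/acceptor 0.25%
each) total 10% — i.e. ~30 coding variants per chromosome — with missense
dominating as expected for EMS point mutations. True variants carry solid
caller evidence (homozygous non-reference fractions, qualities uniform in
20–60, unique placement); a smaller Poisson(60) stream of spurious records
with sub-threshold evidence is mixed in so the calling thresholds are
exercised. The causal lesion is always injected as a homozygous premature
stop at the configured locus. Quality scores are opaque numbers; the
aligner-level semantics behind them are not re-implemented.

### Reproducibility

A single root seed is split into four named substreams consumed in fixed
order — catalog, gametes, pileup, variants — so identical configurations
produce bit-identical tables and each stage can be reproduced in
isolation. All file outputs carry `#` metadata headers (tool version,
seed, thresholds) and contain no timestamps, so reruns are byte-identical.

## The mapping computation

- **Ratios.** HA ratio = hawaiian_reads / total_reads. Zero-depth loci are
  excluded (with a logged count) rather than scored 0 — the ratio is
  undefined without coverage.
- **Filter.** Pass iff hawaiian_reads ≥ 3 AND 0.2 ≤ ratio ≤ 0.6 AND not
  blacklisted. The lower bound suppresses miscall artifacts; the upper
  bound (and the explicit blacklist) removes falsely annotated SNPs riding
  near ratio 1. `fail_reason` is assigned by the first failing rule in the
  fixed order blacklisted → min_reads → below_lower → above_upper so
  audits are deterministic. A looser 0.1–0.8 band is available for scatter
  exports and policy experiments.
- **Interval.** Per chromosome, the mapping interval is the widest gap
  between consecutive passing SNPs. Sentinel entries at bp 1 and the
  chromosome end bound terminal gaps (the two-consecutive-markers rule is
  otherwise silent at chromosome ends); a chromosome with no passing SNPs
  yields the whole chromosome. Ties break toward the leftmost gap, then
  the lexicographically first chromosome. Reported endpoints are the
  flanking passing-SNP positions themselves (not the first positions
  inside the gap); Mb sizes are truncated — not rounded — to two decimals
  (2,067,197 bp → 2.06), the only convention consistent with published
  interval tables, and map-unit sizes are endpoint differences. One
  published row's map-unit width disagrees with its own endpoints by
  0.03 cM; this package always reports endpoint subtraction.
- **Chromosome call.** The chromosome with the widest candidate gap,
  ranked in cM by default to normalize arm/center recombination-rate
  differences (bp ranking is an option). The call is flagged low
  confidence when the widest gap is under twice the runner-up; in null
  (unselected) pools this flag fires in well over half of runs.
- **Variants.** A record is called iff multiplicity ≤ 1, depth ≥ 3, both
  quality scores ≥ 3, and non-reference fraction ≥ 0.8. Classification
  assigns exactly one label: catalog collision → SNP (a strain
  polymorphism, not a lesion), 2 bp intronic flanks of annotated introns →
  splice donor/acceptor, CDS substitutions translated through the standard
  codon table → stop / missense / silent, otherwise noncoding. Candidates
  are the protein-changing classes (missense, stop, splice donor/acceptor,
  never SNP) inside the closed mapping interval. Variants shared with
  previously sequenced datasets are *not* removed — the interval makes
  cross-dataset comparison unnecessary.

## Default parameters

| parameter | default | why |
|---|---|---|
| chromosomes | 6, *C. elegans* lengths, 50 cM each | realistic genome; 50 cM makes r(d)=d/100 exact |
| catalog density | 10⁻³ per bp | ~1 SNP/kb, ~100k loci genome-wide |
| blacklist fraction | 0.004 | "a few hundred" falsely annotated loci out of ~100k |
| n_recombinants | 50 | upper end of the 20–50 design trade-off |
| mean_depth | 20 | one sequencing lane |
| error_rate | 10⁻³ | typical per-base miscall rate |
| causal locus | X:9,941,000 | mid-X, inside the historically mapped region |
| filter | ≥3 HA reads, 0.2–0.6, blacklist on | the strategy's standard criteria |
| caller | mult ≤ 1, depth ≥ 3, quals ≥ 3, non-ref ≥ 0.8 | standard homozygous-call thresholds |

## What the simulator does and does not capture

The generator reproduces the *genetic* structure of the experiment —
linkage, selection, pooling, discrete haplotype counts — and a clean
binomial sequencing model. It does not model alignment artifacts, coverage
bias, overdispersed depth, selfing-induced pool-frequency variance, or
non-uniform recombination landscapes (arms vs. centers) unless an anchor
table supplies one. Passing tests therefore demonstrate correctness of the
method under idealized sequencing, not performance on any particular real
library.

One consequence is worth stating plainly: at 20× depth the detected
interval's edges are usually set by binomial "jackpots" — a locus covered
by a single recombinant haplotype (pool frequency 1/2n) drawing ≥3–4
Hawaiian reads somewhere among the ~350 catalog loci per cM — rather than
by the recombinant-density difference between 20- and 50-animal pools.
Mean interval size does shrink with pool size (≈7.1 vs ≈7.8 cM over 300
paired replicates at these settings), but the per-pair ordering is noisy
(win probability ≈0.55), so paired significance tests on 100 replicates
remain marginal. Real datasets show a larger contrast, consistent with
additional noise sources suppressing edge jackpots there.

## Numerical choices

- Interval arithmetic is integer (bp // 10⁴ / 100), so truncation is exact.
- `cm_to_phys` rounds to the nearest base; round-trip identity holds to
  1 bp on strictly monotone maps (property-tested).
- Crossover breakpoints drawn in cM are clipped into [1, length−1] so both
  segments are non-empty.
- Binomial read splitting samples Hawaiian reads first, then Bristol reads
  from the remainder with the renormalized probability, avoiding a
  per-locus multinomial loop.
- Catalog positions are drawn with replacement and de-duplicated/topped-up,
  which is cheaper than full permutations at realistic densities.

## Known limitations

- No statistical null model for gap sizes: the low-confidence flag is a
  heuristic ratio test, not a p-value.
- Single-CDS, forward-strand toy gene models; real gene structure
  (multi-exon, strand, UTRs) is out of scope.
- Indels, deletions, and deletion-interval mapping are not modeled.
- The `map` CLI subcommand reconstructs the genome from catalog metadata
  or falls back to the default *C. elegans* model; arbitrary genomes
  require the catalog written by `hawmap simulate`/`run` or a YAML config.
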