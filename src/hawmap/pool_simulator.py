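"""Simulation of the pooled-recombinant mapping experiment.

The experiment: a mutagenized Bristol (N2) mutant is crossed to the
polymorphic Hawaiian (CB4856) isolate; F2 progeny showing the mutant
phenotype are singled, their progeny pooled and whole-genome sequenced.
Every selected F2 is homozygous Bristol at the causal locus, so Hawaiian
marker alleles are depleted near the mutation and sit at ~50% at unlinked
loci.

Meiosis model
-------------
One obligate crossover per bivalent, placed uniformly in *genetic* distance,
with the sequenced chromatid recombinant with probability 1/2 (two of the
four chromatids of a bivalent carry the exchange).  This is complete
crossover interference, a good approximation for C. elegans autosomes, and
with 50 cM chromosomes it yields the textbook small-distance relation
r(d) = d/100.

Sequencing model
----------------
Read depth at each catalog locus is Poisson(mean_depth), independent across
loci.  A read reports the Hawaiian base with probability
``f*(1-e) + (1-f)*e/3`` where ``f`` is the pool Hawaiian allele frequency
and ``e`` the per-base miscall rate (a miscall lands on one specific wrong
base with probability e/3); symmetrically for the Bristol base.  Reads
showing neither catalogued base count only toward total depth.  Blacklisted
("falsely annotated") loci are emitted as if the pool were fixed Hawaiian,
which is how they present in real Bristol-derived data.

Pooling is modeled at the F2 allele level.  The bench protocol pools selfed
F3/F4 progeny, but selfing leaves expected allele frequencies unchanged, so
the F2-level model has the same mean structure (documented simplification).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomeModel, SnpCatalog, generate_snp_catalog

__all__ = [
    "BRISTOL",
    "HAWAIIAN",
    "Gamete",
    "F2Genotype",
    "CausalLocus",
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_gamete",
    "simulate_selected_f2",
    "expected_hawaiian_frequency",
    "pool_allele_frequencies",
    "sample_pileup",
    "simulate_background_variants",
    "simulate_experiment",
    "PILEUP_COLUMNS",
    "VARIANT_COLUMNS",
    "VARIANT_CLASSES",
    "CLASS_PROBABILITIES",
]

BRISTOL = 0
HAWAIIAN = 1

SELECTION_MODES = ("homozygous_recessive", "homozygous_only_dominant")

PILEUP_COLUMNS = [
    "chromosome",
    "position",
    "name",
    "hawaiian_base",
    "hawaiian_reads",
    "bristol_base",
    "bristol_reads",
    "total_reads",
]

VARIANT_COLUMNS = [
    "chromosome",
    "position",
    "ref",
    "obs",
    "depth",
    "non_ref_reads",
    "consensus_q",
    "neighboring_q",
    "multiplicity",
    "class",
    "gene",
]

#: Functional classes assigned to mutagen-induced background variants.
VARIANT_CLASSES = (
    "missense",
    "silent",
    "stop",
    "splice_donor",
    "splice_acceptor",
    "noncoding",
)

#: Per-variant class probabilities.  Calibrated so coding classes
#: (missense + silent + stop + splice) total 0.10 — matching the observed
#: mutational load of EMS-mutagenized genomes, ~300 variants per chromosome
#: of which ~30 hit protein-coding sequence — with missense dominating as
#: expected for EMS point mutations.
CLASS_PROBABILITIES = {
    "missense": 0.060,
    "silent": 0.025,
    "stop": 0.010,
    "splice_donor": 0.0025,
    "splice_acceptor": 0.0025,
    "noncoding": 0.900,
}

_NUCS = np.array(["A", "C", "G", "T"])

#: Mean mutagen-induced variants per chromosome, and mean spurious
#: (uncallable) noise records mixed in for the caller to reject.
MEAN_VARIANTS_PER_CHROMOSOME = 300.0
MEAN_NOISE_RECORDS_PER_CHROMOSOME = 60.0


@dataclasses.dataclass(frozen=True)
class CausalLocus:
    """The phenotype-causing lesion being mapped.

    ``selection_mode`` records how homozygotes were obtained: directly by
    phenotype for a recessive allele, or by F3 progeny testing for a dominant
    one.  Either way only homozygous-Bristol F2 animals enter the pool, so
    the two modes are computationally identical.
    """

    chromosome: str
    position: int
    selection_mode: str = "homozygous_recessive"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("causal position must be >= 1")
        if self.selection_mode not in SELECTION_MODES:
            raise ValueError(
                f"selection_mode must be one of {SELECTION_MODES}, "
                f"got {self.selection_mode!r}"
            )


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one pooled-sequencing experiment.

    Defaults follow the experimental design: 50 pooled recombinants at 20x
    mean depth (one Illumina lane), per-base miscall rate 1e-3.
    """

    causal: CausalLocus
    n_recombinants: int = 50
    mean_depth: float = 20.0
    error_rate: float = 0.001
    seed: int = 0
    pool_weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_recombinants < 1:
            raise ValueError("n_recombinants must be >= 1")
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.pool_weights is not None:
            w = np.asarray(self.pool_weights, dtype=float)
            if len(w) != self.n_recombinants:
                raise ValueError("pool_weights length must equal n_recombinants")
            if np.any(w <= 0):
                raise ValueError("pool_weights must be positive")


@dataclasses.dataclass
class Gamete:
    """One chromatid set: per chromosome, segment ends (bp) and origins.

    ``segments[chrom] = (ends, origins)`` where segment i covers
    ``(ends[i-1], ends[i]]`` (first segment starts at bp 1), origins are
    BRISTOL/HAWAIIAN codes and adjacent segments differ in origin, so the
    segments tile [1, physical_length] exactly.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray]]

    def origin_at(self, chromosome: str, positions) -> np.ndarray:
        ends, origins = self.segments[chromosome]
        idx = np.searchsorted(ends, np.asarray(positions), side="left")
        return origins[idx]


@dataclasses.dataclass
class F2Genotype:
    """A selected F2 recombinant: one maternal and one paternal gamete."""

    maternal: Gamete
    paternal: Gamete

    def hawaiian_dosage(self, chromosome: str, positions) -> np.ndarray:
        """Hawaiian allele count (0, 1, 2) at each position."""
        return self.maternal.origin_at(chromosome, positions) + self.paternal.origin_at(
            chromosome, positions
        )


def simulate_gamete(model: GenomeModel, rng: np.random.Generator) -> Gamete:
    """Draw one gamete from an F1 Bristol/Hawaiian heterozygote.

    Per chromosome: with probability 1/2 a non-recombinant chromatid of
    random parental origin; otherwise a single-crossover chromatid whose
    breakpoint is uniform in cM (converted to bp through the genetic map)
    with random phase.
    """
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in model.names:
        length = model.physical_length(chrom)
        gmap = model.genetic_map(chrom)
        if rng.random() < 0.5:  # non-recombinant chromatid
            origin = int(rng.integers(2))
            segments[chrom] = (
                np.array([length], dtype=np.int64),
                np.array([origin], dtype=np.int8),
            )
        else:
            bp_cm = rng.uniform(gmap.cm[0], gmap.cm[-1])
            brk = int(np.clip(gmap.cm_to_phys(bp_cm), 1, length - 1))
            first = int(rng.integers(2))
            segments[chrom] = (
                np.array([brk, length], dtype=np.int64),
                np.array([first, 1 - first], dtype=np.int8),
            )
    return Gamete(segments=segments)


def simulate_selected_f2(
    model: GenomeModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[F2Genotype]:
    """Draw phenotype-selected F2 recombinants by rejection sampling.

    Each accepted F2 carries Bristol origin at the causal locus on both
    gametes (the pool only contains homozygous mutants).  Each candidate
    passes with probability 1/4, so the sampler draws 4 gamete pairs per
    accepted animal on average and always terminates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    causal = config.causal
    if causal.chromosome not in model.names:
        raise ValueError(f"causal chromosome {causal.chromosome!r} not in model")
    if causal.position > model.physical_length(causal.chromosome):
        raise ValueError("causal position beyond chromosome end")
    pos = np.array([causal.position])
    out: list[F2Genotype] = []
    while len(out) < config.n_recombinants:
        mat = simulate_gamete(model, rng)
        pat = simulate_gamete(model, rng)
        if (
            mat.origin_at(causal.chromosome, pos)[0] == BRISTOL
            and pat.origin_at(causal.chromosome, pos)[0] == BRISTOL
        ):
            out.append(F2Genotype(maternal=mat, paternal=pat))
    return out


def expected_hawaiian_frequency(distance_cm: float, linked: bool = True) -> float:
    """Expected pool Hawaiian allele frequency at a marker.

    For a locus ``distance_cm`` from the causal lesion on the same
    chromosome, the frequency equals the recombination fraction under the
    obligate-crossover model: r(d) = d/100 for d <= 50 cM, capped at 0.5.
    Unlinked loci segregate freely: 0.5.
    """
    if distance_cm < 0:
        raise ValueError("distance must be non-negative")
    if not linked:
        return 0.5
    return min(distance_cm, 50.0) / 100.0


def pool_allele_frequencies(
    f2s: Sequence[F2Genotype],
    catalog: SnpCatalog,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Hawaiian allele frequency at every catalog locus, pooled over F2s.

    The frequency is the weighted mean over animals of (Hawaiian dosage)/2;
    weights model unequal animal contributions to the pooled DNA and default
    to equal.
    """
    if weights is None:
        w = np.full(len(f2s), 1.0 / max(len(f2s), 1))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(f2s):
            raise ValueError(
                f"{len(w)} weights for {len(f2s)} genotypes"
            )
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.sum()
    freqs = np.zeros(len(catalog))
    chroms = catalog.df["chromosome"].to_numpy()
    for chrom in catalog.chromosomes:
        mask = chroms == chrom
        pos = catalog.df.loc[mask, "position"].to_numpy(dtype=np.int64)
        acc = np.zeros(pos.size)
        for f2, wi in zip(f2s, w):
            acc += wi * f2.hawaiian_dosage(chrom, pos)
        freqs[mask] = acc / 2.0
    return freqs


def sample_pileup(
    freqs: np.ndarray,
    catalog: SnpCatalog,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample per-locus read counts given pool allele frequencies.

    Returns the 8-field pileup table (one row per catalog locus):
    chromosome, position, name, hawaiian base/reads, bristol base/reads,
    total reads.  Blacklisted loci are sampled with frequency forced to 1.0
    — falsely annotated SNPs read Hawaiian in any Bristol-derived sample.
    """
    if len(freqs) != len(catalog):
        raise ValueError("freqs must align with catalog loci")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = np.asarray(freqs, dtype=float).copy()
    black = catalog.df["blacklisted"].to_numpy(dtype=bool)
    f[black] = 1.0
    e = config.error_rate
    p_haw = f * (1 - e) + (1 - f) * (e / 3.0)
    p_bri = (1 - f) * (1 - e) + f * (e / 3.0)
    total = rng.poisson(config.mean_depth, size=f.size)
    haw = rng.binomial(total, p_haw)
    remainder = total - haw
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bri_given = np.where(p_haw < 1.0, p_bri / (1.0 - p_haw), 0.0)
    bri = rng.binomial(remainder, np.clip(p_bri_given, 0.0, 1.0))
    out = pd.DataFrame(
        {
            "chromosome": catalog.df["chromosome"],
            "position": catalog.df["position"],
            "name": catalog.df["name"],
            "hawaiian_base": catalog.df["hawaiian_base"],
            "hawaiian_reads": haw,
            "bristol_base": catalog.df["bristol_base"],
            "bristol_reads": bri,
            "total_reads": total,
        }
    )
    return out


def _draw_variants(
    rng: np.random.Generator,
    chrom: str,
    length: int,
    n: int,
    mean_depth: float,
    error_rate: float,
    noise: bool,
) -> pd.DataFrame:
    """Draw ``n`` variant records on one chromosome.

    True variants are homozygous with solid caller evidence; ``noise``
    records emulate alignment artifacts: sub-threshold qualities, ambiguous
    non-reference fractions, repeat multiplicity.
    """
    positions = rng.integers(1, length + 1, size=n)
    labels = list(CLASS_PROBABILITIES)
    probs = np.array([CLASS_PROBABILITIES[k] for k in labels])
    classes = rng.choice(labels, size=n, p=probs)
    ref_idx = rng.integers(0, 4, size=n)
    obs_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    depth = np.maximum(rng.poisson(mean_depth, size=n), 1)
    if noise:
        non_ref = rng.binomial(depth, rng.uniform(0.05, 0.5, size=n))
        consensus_q = rng.uniform(0.0, 2.5, size=n)
        neighboring_q = rng.uniform(0.0, 2.5, size=n)
        multiplicity = rng.integers(2, 6, size=n)
    else:
        non_ref = rng.binomial(depth, 1.0 - error_rate)
        consensus_q = rng.uniform(20.0, 60.0, size=n)
        neighboring_q = rng.uniform(20.0, 60.0, size=n)
        multiplicity = np.ones(n, dtype=np.int64)
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position": positions,
            "ref": _NUCS[ref_idx],
            "obs": _NUCS[obs_idx],
            "depth": depth,
            "non_ref_reads": non_ref,
            "consensus_q": np.round(consensus_q, 2),
            "neighboring_q": np.round(neighboring_q, 2),
            "multiplicity": multiplicity,
            "class": classes,
            "gene": ".",
        }
    )


def simulate_background_variants(
    model: GenomeModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the mutagen-induced variant table plus the causal lesion.

    Per chromosome the variant count is Poisson(300) with positions uniform
    and classes drawn from :data:`CLASS_PROBABILITIES` (coding classes sum
    to 10%, i.e. ~30 coding variants per chromosome).  A smaller number of
    spurious records with sub-threshold evidence is mixed in so the caller
    thresholds have work to do.  The causal variant is always injected as a
    homozygous premature ``stop`` at the configured causal locus.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    for chrom in model.names:
        length = model.physical_length(chrom)
        n_true = int(rng.poisson(MEAN_VARIANTS_PER_CHROMOSOME))
        frames.append(
            _draw_variants(
                rng, chrom, length, n_true, config.mean_depth,
                config.error_rate, noise=False,
            )
        )
        n_noise = int(rng.poisson(MEAN_NOISE_RECORDS_PER_CHROMOSOME))
        frames.append(
            _draw_variants(
                rng, chrom, length, n_noise, config.mean_depth,
                config.error_rate, noise=True,
            )
        )
    causal = config.causal
    depth = max(int(rng.poisson(config.mean_depth)), 3)
    causal_row = pd.DataFrame(
        {
            "chromosome": [causal.chromosome],
            "position": [causal.position],
            "ref": ["C"],
            "obs": ["T"],  # EMS G:C -> A:T transition creating a stop
            "depth": [depth],
            "non_ref_reads": [int(rng.binomial(depth, 1.0 - config.error_rate))],
            "consensus_q": [round(float(rng.uniform(20.0, 60.0)), 2)],
            "neighboring_q": [round(float(rng.uniform(20.0, 60.0)), 2)],
            "multiplicity": [1],
            "class": ["stop"],
            "gene": ["causal"],
        }
    )
    frames.append(causal_row)
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chromosome", "position"], kind="stable").reset_index(
        drop=True
    )
    return df[VARIANT_COLUMNS]


@dataclasses.dataclass
class SimulatedExperiment:
    """All artifacts of one simulated pooled-sequencing run."""

    catalog: SnpCatalog
    f2s: list[F2Genotype]
    frequencies: np.ndarray
    pileup: pd.DataFrame
    variants: pd.DataFrame


def simulate_experiment(
    model: GenomeModel,
    config: SimulationConfig,
    catalog: SnpCatalog | None = None,
    density: float = 1e-3,
    blacklist_fraction: float = 0.004,
) -> SimulatedExperiment:
    """Run the full generative model with documented substream seeding.

    The root seed is split into four independent substreams consumed in a
    fixed order — catalog, gametes, pileup, variants — so each stage is
    individually reproducible and supplying a pre-built catalog does not
    perturb the downstream streams.
    """
    ss = np.random.SeedSequence(config.seed)
    cat_ss, gam_ss, pil_ss, var_ss = ss.spawn(4)
    if catalog is None:
        catalog = generate_snp_catalog(
            model,
            density=density,
            blacklist_fraction=blacklist_fraction,
            rng=np.random.default_rng(cat_ss),
        )
    f2s = simulate_selected_f2(model, config, rng=np.random.default_rng(gam_ss))
    freqs = pool_allele_frequencies(f2s, catalog, config.pool_weights)
    pileup = sample_pileup(freqs, catalog, config, rng=np.random.default_rng(pil_ss))
    variants = simulate_background_variants(
        model, config, rng=np.random.default_rng(var_ss)
    )
    return SimulatedExperiment(
        catalog=catalog,
        f2s=f2s,
        frequencies=freqs,
        pileup=pileup,
        variants=variants,
    )
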