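"""Reference genome model, genetic maps, and the Bristol/Hawaiian SNP catalog.

The mapping strategy works on a genome made of a handful of chromosomes,
each carrying a physical coordinate system (bp, 1-based inclusive) and a
genetic one (centimorgans).  Genetic coordinates use a *center-zero*
convention — cM 0 sits near the middle of each chromosome, so map positions
on the left arm are negative — which is the convention used on the
C. elegans genetic map.  The two coordinate systems are tied together by a
piecewise-linear map (a Marey map) defined by anchor points.

The catalog of known Bristol/Hawaiian polymorphisms is the marker set the
whole strategy reads out: roughly one SNP per kilobase, uniformly spread,
~100,000 loci genome-wide.  A small fraction of catalogued loci are
"falsely annotated" — the Bristol stock actually carries the Hawaiian base —
and are flagged as blacklisted so downstream filters can drop them.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "GeneticMap",
    "GenomeModel",
    "SnpLocus",
    "SnpCatalog",
    "build_genome_model",
    "default_elegans_model",
    "generate_snp_catalog",
    "CATALOG_COLUMNS",
]

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])

CATALOG_COLUMNS = [
    "chromosome",
    "position",
    "name",
    "bristol_base",
    "hawaiian_base",
    "blacklisted",
]


@dataclasses.dataclass(frozen=True)
class ChromosomeSpec:
    """Physical and genetic extent of one chromosome.

    ``genetic_length`` defaults to 50 cM: under the single-obligate-crossover
    meiosis model this makes the recombination fraction between two loci
    d cM apart equal d/100, the standard map-distance relation.
    """

    name: str
    physical_length: int
    genetic_length: float = 50.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be non-empty")
        if self.physical_length < 1:
            raise ValueError(
                f"physical_length must be >= 1 bp, got {self.physical_length}"
            )
        if not self.genetic_length > 0:
            raise ValueError(
                f"genetic_length must be positive, got {self.genetic_length}"
            )


@dataclasses.dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear physical<->genetic map for one chromosome.

    Anchors must be strictly increasing in both coordinates, start at
    physical position 1 and end at the chromosome's physical length, so the
    map is invertible and covers the whole chromosome.
    """

    phys: np.ndarray  # bp, int64, strictly increasing, phys[0] == 1
    cm: np.ndarray  # cM, float64, strictly increasing

    def __post_init__(self) -> None:
        phys = np.asarray(self.phys, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        object.__setattr__(self, "phys", phys)
        object.__setattr__(self, "cm", cm)
        if phys.ndim != 1 or phys.shape != cm.shape or phys.size < 2:
            raise ValueError("anchors must be >= 2 paired (bp, cM) points")
        if phys[0] != 1:
            raise ValueError("first anchor must sit at physical position 1")
        if np.any(np.diff(phys) <= 0):
            raise ValueError("anchor physical positions must be strictly increasing")
        if np.any(np.diff(cm) <= 0):
            raise ValueError("anchor cM positions must be strictly increasing")

    @property
    def physical_length(self) -> int:
        return int(self.phys[-1])

    @property
    def genetic_span(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def phys_to_cm(self, position):
        """Interpolate genetic position (cM) at physical ``position`` (bp)."""
        pos = np.asarray(position)
        if np.any(pos < 1) or np.any(pos > self.phys[-1]):
            raise ValueError(
                f"position out of range [1, {self.phys[-1]}]: {position!r}"
            )
        out = np.interp(pos, self.phys, self.cm)
        return float(out) if np.isscalar(position) else out

    def cm_to_phys(self, cm_position):
        """Inverse map: physical bp (rounded to nearest base) at a cM position."""
        cmp_ = np.asarray(cm_position, dtype=np.float64)
        if np.any(cmp_ < self.cm[0]) or np.any(cmp_ > self.cm[-1]):
            raise ValueError(
                f"cM position out of range [{self.cm[0]}, {self.cm[-1]}]: "
                f"{cm_position!r}"
            )
        out = np.rint(np.interp(cmp_, self.cm, self.phys.astype(np.float64)))
        return int(out) if np.isscalar(cm_position) else out.astype(np.int64)


class GenomeModel:
    """A set of chromosomes, each with a validated genetic map."""

    def __init__(
        self,
        chromosomes: Sequence[ChromosomeSpec],
        maps: Mapping[str, GeneticMap],
    ) -> None:
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome name")
        self._specs = {c.name: c for c in chromosomes}
        self._maps = dict(maps)
        for spec in chromosomes:
            gmap = self._maps.get(spec.name)
            if gmap is None:
                raise ValueError(f"no genetic map for chromosome {spec.name}")
            if gmap.physical_length != spec.physical_length:
                raise ValueError(
                    f"map for {spec.name} ends at {gmap.physical_length} bp, "
                    f"chromosome is {spec.physical_length} bp"
                )
            if abs(gmap.genetic_span - spec.genetic_length) > 1e-6:
                raise ValueError(
                    f"map for {spec.name} spans {gmap.genetic_span} cM, "
                    f"expected {spec.genetic_length} cM"
                )

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def spec(self, chromosome: str) -> ChromosomeSpec:
        return self._specs[chromosome]

    def genetic_map(self, chromosome: str) -> GeneticMap:
        return self._maps[chromosome]

    def physical_length(self, chromosome: str) -> int:
        return self._specs[chromosome].physical_length

    def phys_to_cm(self, chromosome: str, position):
        return self._maps[chromosome].phys_to_cm(position)

    def cm_to_phys(self, chromosome: str, cm_position):
        return self._maps[chromosome].cm_to_phys(cm_position)

    @property
    def total_length(self) -> int:
        return sum(c.physical_length for c in self._specs.values())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeModel({len(self._specs)} chromosomes, "
            f"{self.total_length:,} bp)"
        )


def build_genome_model(
    chrom_specs: Sequence[ChromosomeSpec],
    anchor_table: Mapping[str, Sequence[tuple[int, float]]] | None = None,
) -> GenomeModel:
    """Assemble a :class:`GenomeModel` from chromosome specs and optional anchors.

    Without anchors each chromosome gets a uniform two-anchor map spanning
    ``[-genetic_length/2, +genetic_length/2]`` (center-zero convention).
    Anchors, when given, must start at bp 1, end at the chromosome's physical
    length, be strictly increasing in both coordinates, and span exactly the
    chromosome's genetic length.
    """
    if not chrom_specs:
        raise ValueError("need at least one chromosome")
    anchor_table = anchor_table or {}
    maps: dict[str, GeneticMap] = {}
    for spec in chrom_specs:
        anchors = anchor_table.get(spec.name)
        if anchors is None:
            half = spec.genetic_length / 2.0
            maps[spec.name] = GeneticMap(
                phys=np.array([1, spec.physical_length]),
                cm=np.array([-half, +half]),
            )
        else:
            phys = np.array([a[0] for a in anchors], dtype=np.int64)
            cm = np.array([a[1] for a in anchors], dtype=np.float64)
            maps[spec.name] = GeneticMap(phys=phys, cm=cm)
    return GenomeModel(chrom_specs, maps)


#: Approximate chromosome lengths (bp) of the C. elegans reference genome,
#: N2 Bristol; ~100.3 Mb total, so a 1/1,000 bp SNP density yields the
#: ~100,000 catalogued Bristol/Hawaiian polymorphisms.
ELEGANS_CHROMOSOME_LENGTHS = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}


def default_elegans_model(genetic_length: float = 50.0) -> GenomeModel:
    """Six-chromosome C. elegans genome with uniform 50 cM center-zero maps."""
    specs = [
        ChromosomeSpec(name, length, genetic_length)
        for name, length in ELEGANS_CHROMOSOME_LENGTHS.items()
    ]
    return build_genome_model(specs)


@dataclasses.dataclass(frozen=True)
class SnpLocus:
    """One catalogued Bristol/Hawaiian polymorphic position."""

    chromosome: str
    position: int
    name: str
    bristol_base: str
    hawaiian_base: str
    blacklisted: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.bristol_base == self.hawaiian_base:
            raise ValueError("bristol_base and hawaiian_base must differ")


@dataclasses.dataclass
class SnpCatalog:
    """Catalog of known SNP loci, sorted by (chromosome, position).

    Stored columnar (a DataFrame with :data:`CATALOG_COLUMNS`) for speed;
    :meth:`loci` yields per-locus records when convenient.
    """

    df: pd.DataFrame
    density: float

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError("density must be positive")
        missing = [c for c in CATALOG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        df = self.df.loc[:, CATALOG_COLUMNS].reset_index(drop=True)
        key = df[["chromosome", "position"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chromosome, position) in catalog")
        sorted_idx = df.sort_values(["chromosome", "position"], kind="stable").index
        if not np.array_equal(sorted_idx.to_numpy(), np.arange(len(df))):
            df = df.loc[sorted_idx].reset_index(drop=True)
        if (df["bristol_base"] == df["hawaiian_base"]).any():
            raise ValueError("catalog contains loci with identical parental bases")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chromosome"]))

    def positions(self, chromosome: str) -> np.ndarray:
        """Sorted physical positions of catalog loci on ``chromosome``."""
        sel = self.df["chromosome"] == chromosome
        return self.df.loc[sel, "position"].to_numpy(dtype=np.int64)

    def position_set(self) -> set[tuple[str, int]]:
        return set(
            zip(self.df["chromosome"].tolist(), self.df["position"].tolist())
        )

    def loci(self) -> Iterator[SnpLocus]:
        for row in self.df.itertuples(index=False):
            yield SnpLocus(
                chromosome=row.chromosome,
                position=int(row.position),
                name=row.name,
                bristol_base=row.bristol_base,
                hawaiian_base=row.hawaiian_base,
                blacklisted=bool(row.blacklisted),
            )

    @classmethod
    def from_loci(cls, loci: Iterable[SnpLocus], density: float) -> "SnpCatalog":
        rows = [dataclasses.asdict(l) for l in loci]
        df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
        return cls(df=df, density=density)


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Draw ``n`` distinct positions uniformly from [1, length]."""
    if n > length:
        raise ValueError(f"cannot place {n} distinct loci on {length} bp")
    # Draw with replacement and top up; cheaper than permuting whole-chromosome
    # index arrays for realistic densities (~1e-3).
    got = np.unique(rng.integers(1, length + 1, size=n))
    while got.size < n:
        extra = rng.integers(1, length + 1, size=2 * (n - got.size) + 8)
        got = np.unique(np.concatenate([got, extra]))
    if got.size > n:
        got = rng.choice(got, size=n, replace=False)
        got.sort()
    return got.astype(np.int64)


def generate_snp_catalog(
    model: GenomeModel,
    density: float = 1e-3,
    blacklist_fraction: float = 0.004,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SnpCatalog:
    """Generate a synthetic SNP catalog over ``model``.

    Per chromosome the locus count is Poisson with mean ``density *
    physical_length`` and positions are uniform without replacement, emulating
    the uniformly-distributed, ~1/1,000 bp Hawaiian SNP density.  Each locus
    is independently flagged blacklisted ("falsely annotated": the Bristol
    stock carries the Hawaiian base) with probability ``blacklist_fraction``;
    the observed genome-wide blacklist is a few hundred loci out of ~100,000,
    hence the 0.004 default.  Deterministic for a fixed seed.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    if not 0 <= blacklist_fraction < 1:
        raise ValueError(
            f"blacklist_fraction must be in [0, 1), got {blacklist_fraction}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    frames = []
    for chrom in model.names:
        length = model.physical_length(chrom)
        n = int(rng.poisson(density * length))
        n = min(n, length)
        if n == 0:
            continue
        pos = _unique_positions(rng, n, length)
        bristol_idx = rng.integers(0, 4, size=n)
        hawaiian_idx = (bristol_idx + rng.integers(1, 4, size=n)) % 4
        blacklisted = rng.random(n) < blacklist_fraction
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "position": pos,
                    "name": [f"haw_{chrom}_{p}" for p in pos],
                    "bristol_base": _NUCLEOTIDES[bristol_idx],
                    "hawaiian_base": _NUCLEOTIDES[hawaiian_idx],
                    "blacklisted": blacklisted,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:  # pathological tiny genome / density
        df = pd.DataFrame(columns=CATALOG_COLUMNS)
    return SnpCatalog(df=df, density=density)
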