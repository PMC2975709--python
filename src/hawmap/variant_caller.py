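"""Variant calling thresholds, functional classification, candidate filtering.

Calling follows the MAQ-style consensus criteria used for homozygous
mutagen-induced variants: unique placement (loci multiplicity <= 1), depth
>= 3, consensus and neighboring quality scores >= 3, and a non-reference
read fraction >= 0.8.  Quality scores are carried as opaque numbers; their
alignment-level semantics are not re-implemented here.

Classification assigns each called variant exactly one label from
{SNP, missense, stop, splice_donor, splice_acceptor, silent, noncoding}
against a toy gene annotation: a position colliding with a catalogued
Bristol/Hawaiian SNP is labelled ``SNP`` (it is a strain polymorphism, not
a mutagen-induced lesion), splice labels cover the 2 bp intronic flanks of
annotated introns, and coding substitutions are translated through the
standard codon table.

The candidate filter keeps protein-changing classes — missense, stop,
splice donor/acceptor — excluding SNP-labelled records, and restricts them
to the mapping interval.  Variants common to previously sequenced datasets
are deliberately *not* removed: the mapping resolution makes cross-dataset
comparison unnecessary.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_model import SnpCatalog
from .snp_mapper import MappingInterval

__all__ = [
    "CallerThresholds",
    "VariantEvidence",
    "GeneModel",
    "GeneAnnotation",
    "CLASS_LABELS",
    "PROTEIN_CHANGING_CLASSES",
    "call_variant",
    "call_variants",
    "classify_variant",
    "classify_variants",
    "filter_protein_changing",
    "restrict_to_interval",
]

CLASS_LABELS = (
    "SNP",
    "missense",
    "stop",
    "splice_donor",
    "splice_acceptor",
    "silent",
    "noncoding",
)

PROTEIN_CHANGING_CLASSES = frozenset(
    {"missense", "stop", "splice_donor", "splice_acceptor"}
)

_VALID_BASES = frozenset("ACGT")


@dataclasses.dataclass(frozen=True)
class CallerThresholds:
    """Evidence thresholds for calling a homozygous variant."""

    max_loci_multiplicity: int = 1
    min_depth: int = 3
    min_consensus_quality: float = 3.0
    min_neighboring_quality: float = 3.0
    min_nonref_fraction: float = 0.8


@dataclasses.dataclass(frozen=True)
class VariantEvidence:
    """Caller evidence at one putative variant position."""

    chromosome: str
    position: int
    reference_base: str
    observed_base: str
    total_depth: int
    non_reference_reads: int
    consensus_quality: float
    neighboring_quality: float
    loci_multiplicity: int

    def __post_init__(self) -> None:
        if self.non_reference_reads > self.total_depth:
            raise ValueError("non_reference_reads cannot exceed total_depth")
        if self.non_reference_reads < 0 or self.total_depth < 0:
            raise ValueError("read counts must be >= 0")
        if self.consensus_quality < 0 or self.neighboring_quality < 0:
            raise ValueError("quality scores must be >= 0")


def call_variant(
    evidence: VariantEvidence,
    thresholds: CallerThresholds = CallerThresholds(),
) -> bool:
    """Whether the evidence supports a homozygous variant call."""
    if evidence.total_depth == 0:
        raise ValueError("cannot call a variant at zero depth")
    return (
        evidence.loci_multiplicity <= thresholds.max_loci_multiplicity
        and evidence.total_depth >= thresholds.min_depth
        and evidence.consensus_quality >= thresholds.min_consensus_quality
        and evidence.neighboring_quality >= thresholds.min_neighboring_quality
        and evidence.non_reference_reads / evidence.total_depth
        >= thresholds.min_nonref_fraction
    )


def call_variants(
    variants: pd.DataFrame,
    thresholds: CallerThresholds = CallerThresholds(),
) -> pd.DataFrame:
    """Vectorized :func:`call_variant` over a variant table; keeps called rows."""
    depth = variants["depth"].to_numpy()
    if np.any(depth == 0):
        bad = variants.loc[variants["depth"] == 0]
        raise ValueError(
            f"zero-depth variant record(s) at {len(bad)} position(s)"
        )
    called = (
        (variants["multiplicity"] <= thresholds.max_loci_multiplicity)
        & (variants["depth"] >= thresholds.min_depth)
        & (variants["consensus_q"] >= thresholds.min_consensus_quality)
        & (variants["neighboring_q"] >= thresholds.min_neighboring_quality)
        & (variants["non_ref_reads"] / variants["depth"] >= thresholds.min_nonref_fraction)
    )
    return variants.loc[called].reset_index(drop=True)


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Minimal single-CDS gene model on the forward strand.

    ``frame`` counts bases before the first complete codon of the CDS
    interval; ``cds_seq`` is the reference sequence of [cds_start, cds_end].
    Splice donor/acceptor positions are the 2 bp intronic flanks of each
    annotated intron.
    """

    name: str
    chromosome: str
    cds_start: int
    cds_end: int
    frame: int
    cds_seq: str
    donor_positions: tuple[int, ...] = ()
    acceptor_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.cds_end < self.cds_start:
            raise ValueError("cds_end < cds_start")
        if len(self.cds_seq) != self.cds_end - self.cds_start + 1:
            raise ValueError("cds_seq length must match the CDS interval")
        if not 0 <= self.frame <= 2:
            raise ValueError("frame must be 0, 1 or 2")


@dataclasses.dataclass
class GeneAnnotation:
    """Toy gene annotation: a flat list of non-overlapping gene models."""

    genes: list[GeneModel]

    def gene_at(self, chromosome: str, position: int) -> GeneModel | None:
        for g in self.genes:
            if g.chromosome != chromosome:
                continue
            if g.cds_start <= position <= g.cds_end:
                return g
            if position in g.donor_positions or position in g.acceptor_positions:
                return g
        return None


def classify_variant(
    chromosome: str,
    position: int,
    observed_base: str,
    annotation: GeneAnnotation,
    catalog: SnpCatalog | None = None,
    _catalog_positions: set[tuple[str, int]] | None = None,
) -> str:
    """Assign exactly one functional class label to a substitution.

    Precedence: catalog collision (``SNP``) > splice site > CDS codon
    change (stop / missense / silent) > ``noncoding``.
    """
    if observed_base not in _VALID_BASES:
        raise ValueError(f"observed base must be one of A/C/G/T, got {observed_base!r}")
    if _catalog_positions is None and catalog is not None:
        _catalog_positions = catalog.position_set()
    if _catalog_positions is not None and (chromosome, position) in _catalog_positions:
        return "SNP"
    gene = annotation.gene_at(chromosome, position)
    if gene is None:
        return "noncoding"
    if position in gene.donor_positions:
        return "splice_donor"
    if position in gene.acceptor_positions:
        return "splice_acceptor"
    offset = position - gene.cds_start
    if offset < gene.frame:
        return "noncoding"  # partial codon upstream of the first full codon
    codon_index, within = divmod(offset - gene.frame, 3)
    start = gene.frame + 3 * codon_index
    codon = gene.cds_seq[start : start + 3]
    if len(codon) < 3:
        return "noncoding"  # trailing partial codon
    old_aa = str(Seq(codon).translate())
    new_codon = codon[:within] + observed_base + codon[within + 1 :]
    new_aa = str(Seq(new_codon).translate())
    if new_aa == old_aa:
        return "silent"
    if new_aa == "*":
        return "stop"
    return "missense"


def classify_variants(
    variants: pd.DataFrame,
    annotation: GeneAnnotation,
    catalog: SnpCatalog | None = None,
) -> pd.DataFrame:
    """Classify each row of a variant table; adds/overwrites ``class``."""
    cat_pos = catalog.position_set() if catalog is not None else None
    labels = [
        classify_variant(
            row.chromosome,
            int(row.position),
            row.obs,
            annotation,
            _catalog_positions=cat_pos,
        )
        for row in variants.itertuples(index=False)
    ]
    out = variants.copy()
    out["class"] = labels
    return out


def filter_protein_changing(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep missense / stop / splice donor / splice acceptor records.

    SNP-labelled records (strain polymorphisms) are excluded by
    construction; unknown class labels are an error.
    """
    labels = set(variants["class"].unique()) if len(variants) else set()
    unknown = labels - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    keep = variants["class"].isin(PROTEIN_CHANGING_CLASSES)
    return variants.loc[keep].reset_index(drop=True)


def restrict_to_interval(
    variants: pd.DataFrame, interval: MappingInterval
) -> pd.DataFrame:
    """Keep variants inside the mapping interval (closed, 1-based)."""
    keep = (
        (variants["chromosome"] == interval.chromosome)
        & (variants["position"] >= interval.left_bp)
        & (variants["position"] <= interval.right_bp)
    )
    return variants.loc[keep].reset_index(drop=True)
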