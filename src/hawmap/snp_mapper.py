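"""The mapping computation: Hawaiian ratios, filtering, and interval calling.

At every catalogued SNP locus the Hawaiian ratio is
``hawaiian_reads / total_reads``.  Loci unlinked to the selected mutation sit
near 0.5; linked loci are depleted toward 0.  The filter keeps loci that show
*bona fide* Hawaiian signal — at least 3 Hawaiian reads and a ratio in
[0.2, 0.6] by default.  The lower bound keeps random miscalls from
masquerading as Hawaiian sequence; the upper bound (plus an explicit
blacklist) removes falsely annotated SNPs, where Bristol stocks actually
carry the "Hawaiian" base and the ratio rides near 1.

The mapping interval on each chromosome is the widest gap between
consecutive passing SNPs (with sentinels at the chromosome termini so a
depleted terminal region still yields a bounded interval), and the mutation-
bearing chromosome is the one with the widest gap in genetic distance.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomeModel, SnpCatalog

__all__ = [
    "FilterPolicy",
    "MappingInterval",
    "ChromosomeCall",
    "FAIL_REASONS",
    "compute_ratios",
    "apply_filter",
    "passing_records",
    "find_mapping_interval",
    "call_mutation_chromosome",
    "interval_size_mb",
    "interval_size_cm",
    "count_passing_per_chromosome",
    "export_scatter",
    "plot_scatter",
]

logger = logging.getLogger(__name__)

FAIL_REASONS = ("blacklisted", "min_reads", "below_lower", "above_upper", "none")


@dataclasses.dataclass(frozen=True)
class FilterPolicy:
    """Which SNP loci count as genuine Hawaiian signal.

    Defaults are the standard criteria: >= 3 Hawaiian reads, ratio within
    [0.2, 0.6], and known falsely-annotated loci dropped.  A looser
    0.1-0.8 band trades specificity for marker density.
    """

    min_ha_reads: int = 3
    lower: float = 0.2
    upper: float = 0.6
    use_blacklist: bool = True

    def __post_init__(self) -> None:
        if self.min_ha_reads < 0:
            raise ValueError("min_ha_reads must be >= 0")
        if not 0 <= self.lower < self.upper <= 1:
            raise ValueError(
                f"need 0 <= lower < upper <= 1, got [{self.lower}, {self.upper}]"
            )


@dataclasses.dataclass(frozen=True)
class MappingInterval:
    """A candidate mutation-bearing region on one chromosome.

    ``size_mb`` is the bp width truncated (not rounded) to 2 decimals;
    ``size_cm`` is the difference of the endpoint genetic positions.
    """

    chromosome: str
    left_bp: int
    right_bp: int
    left_cm: float
    right_cm: float
    size_mb: float
    size_cm: float

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.left_bp <= position <= self.right_bp
        )


@dataclasses.dataclass(frozen=True)
class ChromosomeCall:
    """Result of ranking per-chromosome gaps."""

    chromosome: str
    interval: MappingInterval
    low_confidence: bool
    note: str


def _check_sorted(df: pd.DataFrame) -> None:
    order = df.sort_values(["chromosome", "position"], kind="stable").index
    if not np.array_equal(order.to_numpy(), df.index.to_numpy()):
        raise ValueError("pileup records must be sorted by (chromosome, position)")


def compute_ratios(pileup: pd.DataFrame) -> pd.DataFrame:
    """Attach the Hawaiian ratio; drop zero-depth loci.

    The ratio is undefined without coverage, so zero-depth records are
    excluded (the dropped count is logged) rather than treated as ratio 0.
    """
    _check_sorted(pileup)
    zero = pileup["total_reads"] == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.info("excluded %d zero-depth loci of %d", n_zero, len(pileup))
    out = pileup.loc[~zero].reset_index(drop=True).copy()
    out["ha_ratio"] = out["hawaiian_reads"] / out["total_reads"]
    return out


def apply_filter(
    ratios: pd.DataFrame,
    policy: FilterPolicy = FilterPolicy(),
    catalog: SnpCatalog | None = None,
) -> pd.DataFrame:
    """Annotate every record with ``passes_filter`` and ``fail_reason``.

    A record passes iff hawaiian_reads >= min_ha_reads, lower <= ratio <=
    upper, and (when the blacklist is in use) the locus is not flagged.
    ``fail_reason`` reports the first failing rule in the fixed order
    blacklisted -> min_reads -> below_lower -> above_upper so audits are
    deterministic.  Blacklist flags come from ``catalog`` (joined on
    chromosome and position) or from a pre-existing ``blacklisted`` column.
    """
    out = ratios.copy()
    if policy.use_blacklist:
        if catalog is not None:
            flags = catalog.df[["chromosome", "position", "blacklisted"]]
            out = out.merge(
                flags, on=["chromosome", "position"], how="left", suffixes=("", "_cat")
            )
            if "blacklisted_cat" in out.columns:  # input already carried flags
                out["blacklisted"] = out.pop("blacklisted_cat")
            out["blacklisted"] = out["blacklisted"].fillna(False).astype(bool)
        elif "blacklisted" in out.columns:
            out["blacklisted"] = out["blacklisted"].astype(bool)
        else:
            out["blacklisted"] = False
    else:
        out["blacklisted"] = False
    black = out["blacklisted"].to_numpy()
    few = out["hawaiian_reads"].to_numpy() < policy.min_ha_reads
    low = out["ha_ratio"].to_numpy() < policy.lower
    high = out["ha_ratio"].to_numpy() > policy.upper
    out["fail_reason"] = np.select(
        [black, few, low, high],
        ["blacklisted", "min_reads", "below_lower", "above_upper"],
        default="none",
    )
    out["passes_filter"] = out["fail_reason"] == "none"
    return out


def passing_records(annotated: pd.DataFrame) -> pd.DataFrame:
    """The passing subset of an :func:`apply_filter` result."""
    return annotated.loc[annotated["passes_filter"]].reset_index(drop=True)


def interval_size_mb(left_bp: int, right_bp: int, decimals: int = 2) -> float:
    """Interval width in Mb, truncated to ``decimals`` decimal places.

    Truncation (floor), not rounding: e.g. a 2,067,197 bp interval is
    reported as 2.06 Mb, and a 4,924,346 bp one as 4.9 Mb at one decimal.
    """
    if right_bp <= left_bp:
        raise ValueError(f"reversed endpoints ({left_bp}, {right_bp})")
    scale = 10**decimals
    return ((right_bp - left_bp) // (10**6 // scale)) / scale


def interval_size_cm(left_cm: float, right_cm: float) -> float:
    """Interval width in map units: the endpoint difference, to 2 decimals."""
    if right_cm < left_cm:
        raise ValueError(f"reversed endpoints ({left_cm}, {right_cm})")
    return round(right_cm - left_cm, 2)


def _largest_gap(positions: np.ndarray, length: int) -> tuple[int, int]:
    """Widest gap between consecutive entries after adding terminal sentinels.

    Ties break toward the leftmost gap.  With no positions at all the whole
    chromosome [1, length] is the gap.
    """
    aug = np.concatenate(([1], np.sort(np.asarray(positions, dtype=np.int64)), [length]))
    diffs = np.diff(aug)
    i = int(np.argmax(diffs))  # argmax returns the first (leftmost) maximum
    return int(aug[i]), int(aug[i + 1])


def find_mapping_interval(
    passing: pd.DataFrame | Mapping[str, Sequence[int]],
    model: GenomeModel,
) -> dict[str, MappingInterval]:
    """Per-chromosome candidate interval: the widest gap between passing SNPs.

    ``passing`` is either a filtered record table (with chromosome/position
    columns) or a mapping of chromosome -> positions.  Sentinels at bp 1 and
    the chromosome end bound terminal gaps; a chromosome without passing
    SNPs yields the whole chromosome.  Endpoints are the flanking entries
    (passing SNP positions, or sentinels when terminal).
    """
    if isinstance(passing, pd.DataFrame):
        per_chrom = {
            chrom: grp["position"].to_numpy(dtype=np.int64)
            for chrom, grp in passing.groupby("chromosome", sort=False)
        }
    else:
        per_chrom = {k: np.asarray(v, dtype=np.int64) for k, v in passing.items()}
    out: dict[str, MappingInterval] = {}
    for chrom in model.names:
        length = model.physical_length(chrom)
        pos = per_chrom.get(chrom, np.empty(0, dtype=np.int64))
        left, right = _largest_gap(pos, length)
        left_cm = model.phys_to_cm(chrom, left)
        right_cm = model.phys_to_cm(chrom, right)
        out[chrom] = MappingInterval(
            chromosome=chrom,
            left_bp=left,
            right_bp=right,
            left_cm=round(left_cm, 4),
            right_cm=round(right_cm, 4),
            size_mb=interval_size_mb(left, right),
            size_cm=interval_size_cm(left_cm, right_cm),
        )
    return out


def call_mutation_chromosome(
    candidates: Mapping[str, MappingInterval],
    rank_by: str = "cm",
) -> ChromosomeCall:
    """Pick the mutation-bearing chromosome: the widest candidate gap.

    Gaps are ranked in genetic distance by default, which normalizes the
    chromosome-arm recombination-rate differences that distort physical gap
    widths; ``rank_by='bp'`` ranks physically instead.  The call is flagged
    low-confidence when the widest gap is less than twice the runner-up —
    in a clean selected pool the depleted region dwarfs every unlinked gap.
    """
    if not candidates:
        raise ValueError("no candidate intervals")
    if rank_by not in ("cm", "bp"):
        raise ValueError("rank_by must be 'cm' or 'bp'")

    def width(iv: MappingInterval) -> float:
        return iv.right_cm - iv.left_cm if rank_by == "cm" else iv.right_bp - iv.left_bp

    ranked = sorted(
        candidates.items(), key=lambda kv: (-width(kv[1]), kv[0])
    )
    best_chrom, best = ranked[0]
    if len(ranked) > 1:
        second = width(ranked[1][1])
        low_conf = width(best) < 2.0 * second
        note = (
            f"widest gap {width(best):.3f} {rank_by} on {best_chrom}; "
            f"runner-up {second:.3f} {rank_by} on {ranked[1][0]}"
        )
    else:
        low_conf = False
        note = f"single chromosome {best_chrom}"
    if low_conf:
        note += " — LOW CONFIDENCE (widest gap < 2x runner-up)"
    return ChromosomeCall(
        chromosome=best_chrom, interval=best, low_confidence=low_conf, note=note
    )


def count_passing_per_chromosome(
    passing: pd.DataFrame,
    chromosomes: Sequence[str] | None = None,
) -> dict[str, int]:
    """Passing-SNP tally per chromosome (zeros included when names given)."""
    counts = passing.groupby("chromosome", sort=False).size().to_dict()
    if chromosomes is not None:
        counts = {c: int(counts.get(c, 0)) for c in chromosomes}
    return {k: int(v) for k, v in counts.items()}


def _band_column(lower: float, upper: float) -> str:
    return f"in_{lower:g}_{upper:g}"


def export_scatter(
    ratios: pd.DataFrame,
    bands: Sequence[tuple[float, float]] = ((0.2, 0.6), (0.1, 0.8)),
) -> pd.DataFrame:
    """Plot-ready table of per-locus ratios with band-membership flags.

    One row per ratio record; each ``(lower, upper)`` band contributes a
    boolean column flagging records whose ratio falls inside it.
    """
    cols = ["chromosome", "position", "ha_ratio"]
    out = ratios.loc[:, cols].copy()
    r = out["ha_ratio"].to_numpy() if len(out) else np.empty(0)
    for lower, upper in bands:
        if not 0 <= lower < upper <= 1:
            raise ValueError(f"invalid band ({lower}, {upper})")
        out[_band_column(lower, upper)] = (r >= lower) & (r <= upper)
    return out


def plot_scatter(
    scatter: pd.DataFrame,
    model: GenomeModel,
    path: str,
    causal: tuple[str, int] | None = None,
) -> None:
    """Render per-chromosome XY ratio scatters to ``path`` (one panel each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = model.names
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(9, 1.8 * len(chroms)), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, chrom in zip(axes, chroms):
        sel = scatter["chromosome"] == chrom
        ax.plot(
            scatter.loc[sel, "position"] / 1e6,
            scatter.loc[sel, "ha_ratio"],
            ".",
            ms=2,
            alpha=0.5,
        )
        ax.set_ylabel(chrom)
        ax.set_ylim(-0.05, 1.05)
        ax.set_xlim(0, model.physical_length(chrom) / 1e6)
        if causal is not None and causal[0] == chrom:
            ax.axvline(causal[1] / 1e6, color="red", lw=1)
    axes[-1].set_xlabel("position (Mb)")
    fig.suptitle("Hawaiian read ratio at catalogued SNP loci")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
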