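"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` on the plus
strand. Input dialects (1-based methylome tables, BED, GTF) are normalised to
this convention at read time and never leak past :mod:`methdiff.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class MethdiffError(Exception):
    """Base class for errors raised by this package."""


class FormatError(MethdiffError):
    """An input file violates its declared format or an invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths defining the coordinate space.

    Any assembly (or synthetic genome) can be used; nothing in the pipeline
    assumes a particular reference.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(lengths.values()))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)


@dataclass(frozen=True)
class CpGRecord:
    """Bisulfite read counts at one CpG (position of the plus-strand C).

    Counts from the two strands are assumed to have been merged upstream;
    ``meth`` is the number of reads supporting methylation (non-converted
    cytosines), ``total`` the number of reads covering the site.
    """

    chrom: str
    pos: int
    meth: int
    total: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not (0 <= self.meth <= self.total):
            raise ValueError(
                f"invalid counts meth={self.meth}, total={self.total} "
                f"at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene locus. ``tss`` is always the transcription start.

    For plus-strand genes ``tss < tes``; for minus-strand genes the start
    site has the larger coordinate, so ``tes < tss``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: plus-strand gene needs tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise ValueError(f"{self.gene_id}: minus-strand gene needs tes < tss")

    @property
    def span(self) -> tuple[int, int]:
        """Leftmost/rightmost coordinates of the locus, strand-agnostic."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))


@dataclass(frozen=True)
class SignalSite:
    """A ChIP signal-site interval (e.g. a TF-binding or histone-mark peak)."""

    chrom: str
    start: int
    end: int
    mark: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"site needs start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class Region:
    """A labelled genomic window owned by a gene or a site."""

    chrom: str
    start: int
    end: int
    label: str = ""
    owner: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"region needs start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionMethylation:
    """Region-level methylation: the unweighted mean of per-CpG mC values.

    ``mc_ratio`` is NaN when no covered CpG falls in the region, in which
    case ``n_cpg`` is 0.
    """

    region: Region
    mc_ratio: float
    n_cpg: int

    @property
    def defined(self) -> bool:
        return self.n_cpg >= 1 and not math.isnan(self.mc_ratio)


@dataclass(frozen=True)
class NullThresholds:
    """Percentile cut-offs of the random-loci null delta distribution."""

    hypo_cut: float
    hyper_cut: float
    n_null: int
    percentile: float = 5.0

    def __post_init__(self) -> None:
        if self.hypo_cut > self.hyper_cut:
            raise ValueError("hypo_cut must be <= hyper_cut")


@dataclass(frozen=True)
class CpGContentClass:
    """CpG dinucleotide density of a window and its low/high class."""

    content: float
    cls: str
    threshold: float = 0.03


@dataclass(frozen=True)
class RepresentationResult:
    """One-sided binomial representation test for a mark's DM sites."""

    mark: str
    k: int
    n: int
    p0: float
    enrichment: float
    p_over: float
    p_under: float


@dataclass(frozen=True)
class FisherEnrichment:
    """DE-within-DM 2x2 Fisher exact test result."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_enrichment: float
    p_depletion: float


@dataclass(frozen=True)
class DecileReport:
    """FPKM summary for a methylation-ranked gene group vs all genes."""

    group: str
    n: int
    median_fpkm: float
    wilcoxon_p: float = field(default=float("nan"))
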