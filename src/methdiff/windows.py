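"""Promoter and gene-body windows, and CpG-content classification.

Promoters span 1,000 bp upstream to 500 bp downstream of the transcription
start site; gene bodies run from 2,000 bp downstream of the TSS to the
transcription end site. Both are strand-aware: minus-strand windows mirror
the plus-strand definitions. Gene bodies that would be empty (TES within
2,000 bp of the TSS) are excluded as too short. Promoter windows are clamped
to chromosome bounds rather than excluded.

CpG content is the density of plus-strand CpG dinucleotides per bp of
window; windows split into low/high classes at a threshold of 0.03, with the
boundary value assigned to the high class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import REGION_COLUMNS
from .models import CpGContentClass, GeneModel, GenomeLayout, Region

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500
GENE_BODY_TSS_OFFSET = 2000
CPG_CONTENT_THRESHOLD = 0.03


def promoter_region(
    gene: GeneModel,
    layout: GenomeLayout | None = None,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> Region:
    """The promoter window around the TSS, clamped to the chromosome."""
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(start, 0)
    if layout is not None:
        end = min(end, layout.length_of(gene.chrom))
    return Region(gene.chrom, start, end, label="promoter", owner=gene.gene_id)


def gene_body_region(
    gene: GeneModel,
    layout: GenomeLayout | None = None,
    tss_offset: int = GENE_BODY_TSS_OFFSET,
) -> Region | None:
    """The gene-body window, or None when the locus is too short to hold it."""
    if gene.strand == "+":
        start, end = gene.tss + tss_offset, gene.tes
    else:
        start, end = gene.tes, gene.tss - tss_offset
    start = max(start, 0)
    if layout is not None:
        end = min(end, layout.length_of(gene.chrom))
    if start >= end:
        return None
    return Region(gene.chrom, start, end, label="gene_body", owner=gene.gene_id)


def build_windows(
    genes: list[GeneModel], layout: GenomeLayout | None = None
) -> pd.DataFrame:
    """Promoter and gene-body windows for a gene set, as a region table."""
    rows = []
    n_short = 0
    for gene in genes:
        p = promoter_region(gene, layout)
        rows.append((p.chrom, p.start, p.end, p.owner, p.label))
        b = gene_body_region(gene, layout)
        if b is None:
            n_short += 1
        else:
            rows.append((b.chrom, b.start, b.end, b.owner, b.label))
    if n_short:
        logger.info("build_windows: %d genes too short for a gene-body window", n_short)
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def cpg_content(
    region: Region,
    cpg_positions: np.ndarray | None = None,
    sequence: str | None = None,
    threshold: float = CPG_CONTENT_THRESHOLD,
) -> CpGContentClass:
    """CpG dinucleotide density of a window and its low/high class.

    Supply either ``cpg_positions`` (sorted plus-strand C positions for the
    region's chromosome) or ``sequence`` (the region's own sequence, in which
    only CpGs fully inside the window are counted). Content equal to the
    threshold classifies as high.
    """
    length = len(region)
    if length <= 0:
        raise ValueError("region length must be positive")
    if (cpg_positions is None) == (sequence is None):
        raise ValueError("provide exactly one of cpg_positions or sequence")
    if cpg_positions is not None:
        pos = np.asarray(cpg_positions)
        n = int(np.searchsorted(pos, region.end) - np.searchsorted(pos, region.start))
    else:
        n = sequence.upper().count("CG")
    content = n / length
    cls = "high" if content >= threshold else "low"
    return CpGContentClass(content=content, cls=cls, threshold=threshold)


def classify_promoters(
    genes: list[GeneModel],
    cpg_positions: dict[str, np.ndarray],
    layout: GenomeLayout | None = None,
    threshold: float = CPG_CONTENT_THRESHOLD,
) -> pd.Series:
    """Low/high CpG-content class per gene promoter, indexed by gene id."""
    classes = {}
    for gene in genes:
        region = promoter_region(gene, layout)
        cc = cpg_content(
            region,
            cpg_positions=cpg_positions.get(gene.chrom, np.empty(0, dtype=np.int64)),
            threshold=threshold,
        )
        classes[gene.gene_id] = cc.cls
    return pd.Series(classes, name="cpg_class")
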