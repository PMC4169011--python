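"""Joining methylation calls with expression classes and ChIP signal sites.

Sites are associated with genes lying within 3,000 bp (interval-to-interval
distance by default). Over/under-representation of differentially methylated
sites among a mark's site set is an exact one-sided binomial test with a 5%
occurrence probability — the fraction expected to be called by chance under
the percentile null. Enrichment of differential expression among
differentially methylated genes is an exact Fisher test on the 2x2
membership table. The enrichment grid visualises where a gene class
concentrates in the (mC_A, mC_B) plane relative to the background density of
all genes. Marker genes are those both linked to a hypomethylated site and
transcriptionally activated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import FisherEnrichment, GeneModel, MethdiffError, RepresentationResult

logger = logging.getLogger(__name__)

MAX_ASSOCIATION_DIST = 3000
OCCURRENCE_P0 = 0.05


def _gene_frame(genes) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        return genes
    rows = [(g.gene_id, g.chrom, g.strand, g.tss, g.tes) for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])


def associate_sites(
    sites: pd.DataFrame,
    genes: list[GeneModel] | pd.DataFrame,
    max_dist: int = MAX_ASSOCIATION_DIST,
    anchor: str = "span",
) -> pd.DataFrame:
    """Link each site to every gene within ``max_dist`` bp (many-to-many).

    ``anchor='span'`` measures the gap between the site interval and the
    gene span [min(tss,tes), max(tss,tes)); ``anchor='tss'`` measures to the
    TSS point. Overlap counts as distance 0. Returns a DataFrame with
    site_id, gene_id and distance.
    """
    if anchor not in ("span", "tss"):
        raise ValueError("anchor must be 'span' or 'tss'")
    gdf = _gene_frame(genes)
    sites = sites.reset_index(drop=True)
    if "site_id" not in sites.columns:
        sites = sites.copy()
        sites["site_id"] = [f"site_{i}" for i in range(len(sites))]
    trees: dict[str, IntervalTree] = {}
    spans: dict[str, tuple[int, int]] = {}
    for row in gdf.itertuples(index=False):
        if anchor == "span":
            lo, hi = min(row.tss, row.tes), max(row.tss, row.tes)
        else:
            lo, hi = row.tss, row.tss + 1
        spans[row.gene_id] = (lo, hi)
        # pad by max_dist + 1: half-open tree intervals must still overlap a
        # site whose gap to the span is exactly max_dist
        trees.setdefault(row.chrom, IntervalTree()).addi(
            lo - max_dist - 1, hi + max_dist + 1, row.gene_id
        )
    links = []
    for row in sites.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            lo, hi = spans[iv.data]
            gap = max(lo - row.end, row.start - hi, 0)
            if gap <= max_dist:
                links.append((row.site_id, iv.data, gap))
    out = pd.DataFrame(links, columns=["site_id", "gene_id", "distance"])
    logger.info(
        "associate_sites: %d links for %d sites and %d genes (<=%d bp)",
        len(out), len(sites), len(gdf), max_dist,
    )
    return out.sort_values(["site_id", "gene_id"], kind="mergesort").reset_index(drop=True)


def representation_test(
    k: int, n: int, p0: float = OCCURRENCE_P0, mark: str = ""
) -> RepresentationResult:
    """Exact one-sided binomial tails for k DM sites out of n.

    ``p_over = P(X >= k)`` and ``p_under = P(X <= k)`` for X ~ Bin(n, p0);
    enrichment is the observed/expected ratio ``k / (n * p0)``.
    """
    if n <= 0:
        raise MethdiffError("representation test needs n > 0 sites")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    return RepresentationResult(
        mark=mark,
        k=int(k),
        n=int(n),
        p0=float(p0),
        enrichment=float(k / (n * p0)),
        p_over=float(stats.binom.sf(k - 1, n, p0)),
        p_under=float(stats.binom.cdf(k, n, p0)),
    )


def de_dm_enrichment(
    dm_genes: set[str], de_genes: set[str], universe: set[str]
) -> FisherEnrichment:
    """Fisher exact test of a DE gene class within a DM gene class.

    Builds the 2x2 table (in/out DM) x (in/out DE) over the universe and
    reports the odds ratio with one-sided exact p-values for enrichment
    (more overlap than expected) and depletion. An odds ratio of infinity
    (the DM set exhausts the off-diagonal) makes depletion impossible and is
    reported as such via p_depletion = 1.
    """
    if not universe:
        raise MethdiffError("empty gene universe")
    dm = set(dm_genes) & set(universe)
    de = set(de_genes) & set(universe)
    if dm - set(universe) or de - set(universe):
        raise ValueError("gene sets must be subsets of the universe")
    a = len(dm & de)
    b = len(dm - de)
    c = len(de - dm)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds = (a * d / (b * c)) if b * c > 0 else float("inf")
    p_enrich = float(stats.fisher_exact(table, alternative="greater")[1])
    p_deplete = float(stats.fisher_exact(table, alternative="less")[1])
    return FisherEnrichment(
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        p_enrichment=p_enrich,
        p_depletion=p_deplete,
    )


class EnrichmentGrid:
    """Gene-class density over the (mC_A, mC_B) plane, relative to background.

    Per bin: (class fraction) / (background fraction), computed over bins
    whose background count reaches ``min_bg``; sparser bins are masked
    (NaN). Fractions are renormalised over unmasked bins, so the
    background-weighted mean of unmasked enrichments is exactly 1.
    """

    def __init__(self, edges, enrichment, bg_counts, class_counts, mask):
        self.edges = edges
        self.enrichment = enrichment
        self.bg_counts = bg_counts
        self.class_counts = class_counts
        self.mask = mask

    def peak_bin(self) -> tuple[float, float]:
        """Centre (mC_A, mC_B) of the unmasked bin with maximal enrichment."""
        filled = np.where(self.mask, -np.inf, self.enrichment)
        i, j = np.unravel_index(np.nanargmax(filled), filled.shape)
        centres = (self.edges[:-1] + self.edges[1:]) / 2
        return float(centres[i]), float(centres[j])


def enrichment_grid(
    mc_a: pd.Series,
    mc_b: pd.Series,
    class_genes: set[str] | list[str],
    bin_width: float = 0.05,
    min_bg: int = 5,
) -> EnrichmentGrid:
    """Relative density of a gene class in the differential-methylation plane.

    ``mc_a`` and ``mc_b`` are per-gene region mC ratios in the two
    conditions (indexed by gene id); the background is every gene defined in
    both.
    """
    shared = mc_a.dropna().index.intersection(mc_b.dropna().index)
    class_genes = [g for g in class_genes if g in shared]
    if not class_genes:
        raise MethdiffError("no class genes with defined methylation in both conditions")
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    bg, _, _ = np.histogram2d(
        mc_a.loc[shared].to_numpy(), mc_b.loc[shared].to_numpy(), bins=(edges, edges)
    )
    cl, _, _ = np.histogram2d(
        mc_a.loc[class_genes].to_numpy(), mc_b.loc[class_genes].to_numpy(), bins=(edges, edges)
    )
    mask = bg < min_bg
    bg_tot = bg[~mask].sum()
    cl_tot = cl[~mask].sum()
    if bg_tot == 0 or cl_tot == 0:
        raise MethdiffError("all bins masked; lower min_bg or widen bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (cl / cl_tot) / (bg / bg_tot)
    enr[mask] = np.nan
    return EnrichmentGrid(edges, enr, bg, cl, mask)


def select_marker_genes(
    site_calls: pd.DataFrame,
    links: pd.DataFrame,
    de_classes: pd.DataFrame,
) -> list[str]:
    """Genes linked to >=1 hypomethylated signal site and activated.

    ``site_calls`` carries per-site DM calls (columns owner/site_id and
    call), ``links`` the site-gene associations, ``de_classes`` the
    per-gene DE calls. Output is deterministic and sorted.
    """
    id_col = "site_id" if "site_id" in site_calls.columns else "owner"
    hypo_sites = set(site_calls.loc[site_calls["call"] == "hypo", id_col])
    linked = set(links.loc[links["site_id"].isin(hypo_sites), "gene_id"])
    activated = set(de_classes.index[de_classes["call"] == "activated"])
    selected = sorted(linked & activated)
    logger.info(
        "select_marker_genes: %d hypo sites -> %d linked genes -> %d activated markers",
        len(hypo_sites), len(linked), len(selected),
    )
    return selected
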