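"""Synthetic three-condition cohort with known ground truth.

The generator emulates the data layers a methylome/transcriptome/cistrome
integration consumes — per-CpG bisulfite counts, an FPKM matrix, and ChIP
signal-site intervals — for a toy genome, under a design mirroring a
stem-cell study: a baseline somatic condition (ADSC-like), a reprogrammed
condition (iPSC-like) with many planted promoter DMRs, and a differentiated
condition (FatC-like) that differs from baseline mainly at planted
intergenic hypomethylated regions hosting binding sites of one TF-like mark.

Methylation counts are beta-binomial: each CpG's underlying methylation
level is drawn around its region's mean (promoter and gene-body means are
coupled to the gene's expression rank, in opposite directions), read depth
is Poisson at 28x coverage, and methylated-read counts are binomial.
Expression is log-normal FPKM with multiplicative noise; planted
differential genes shift by a log2 fold, and a configurable fraction of
genes owning hypomethylated promoters/sites is assigned activation so the
methylation-expression couplings are recoverable downstream.

All randomness flows from one ``numpy.random.Generator``; the same seed
reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import GeneModel, GenomeLayout, MethdiffError
from .windows import gene_body_region, promoter_region

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkSpec:
    """One ChIP mark's site layer.

    ``frac_in_dmr`` of the sites are placed inside planted intergenic
    hypomethylated regions; the rest are uniform over the genome outside all
    planted DMRs. ``meth_level``, when set, pins the methylation of the
    non-DMR site footprints (stably low for activation-mark analogs, stably
    high for repression-mark analogs).
    """

    n_sites: int
    frac_in_dmr: float = 0.0
    length_range: tuple[int, int] = (200, 800)
    meth_level: float | None = None


def _default_marks() -> dict[str, MarkSpec]:
    return {
        "PPARG": MarkSpec(2000, frac_in_dmr=0.15),
        "H3K4me3": MarkSpec(1500, frac_in_dmr=0.0, meth_level=0.10),
        "H3K27me3": MarkSpec(1500, frac_in_dmr=0.0, meth_level=0.85),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (defaults are the cohort)."""

    conditions: tuple[str, ...] = ("iPSC", "ADSC", "FatC")
    baseline_condition: str = "ADSC"
    # genome
    n_chrom: int = 2
    chrom_length: int = 3_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (4500, 8000)
    min_flank: int = 3500
    extra_gap_mean: float = 1500.0
    cpg_density: float = 0.015
    high_cpg_fraction: float = 0.5
    high_cpg_promoter_density: float = 0.05
    # methylome noise model
    mean_coverage: float = 28.0
    dispersion: float = 50.0          # beta-binomial concentration
    meth_noise_sd: float = 0.04       # per-region jitter of the mean level
    # baseline region methylation vs expression-rank coupling (intercept, slope)
    high_cpg_promoter_meth: tuple[float, float] = (0.50, -0.45)
    low_cpg_promoter_meth: tuple[float, float] = (0.95, -0.60)
    gene_body_meth: tuple[float, float] = (0.35, 0.50)
    intergenic_meth_beta: tuple[float, float] = (6.0, 1.5)
    # planted promoter DMRs per non-baseline condition: (n_hypo, n_hyper)
    promoter_dmrs: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"iPSC": (40, 20), "FatC": (6, 3)}
    )
    dmr_delta: float = 0.4
    # planted intergenic hypo-DMRs hosting TF-like binding sites
    n_intergenic_dmrs: int = 60
    intergenic_dmr_length: int = 1000
    intergenic_dmr_condition: str = "FatC"
    intergenic_dmr_delta: float = 0.4
    intergenic_dmr_meth: float = 0.75
    marks: dict[str, MarkSpec] = field(default_factory=_default_marks)
    # expression
    log10_fpkm_mean: float = 0.8
    log10_fpkm_sd: float = 0.6
    expr_noise_sd: float = 0.08       # log10-scale multiplicative noise
    de_log2_fold: float = 2.0
    n_extra_de: int = 40
    dmr_de_coupling: float = 0.6
    silent_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_condition not in self.conditions:
            raise ValueError("baseline_condition must be one of conditions")
        for frac in (self.high_cpg_fraction, self.dmr_de_coupling, self.silent_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for spec in self.marks.values():
            if not 0 <= spec.frac_in_dmr <= 1:
                raise ValueError("frac_in_dmr must lie in [0, 1]")
        if not 0 < self.dmr_delta < 1 or not 0 < self.intergenic_dmr_delta < 1:
            raise ValueError("DMR deltas must keep mC levels inside [0, 1]")
        if not 0 <= self.intergenic_dmr_meth - self.intergenic_dmr_delta:
            raise ValueError("intergenic DMR delta would push mC below 0")

    def null(self) -> "SimulationConfig":
        """A copy with nothing planted: pure noise between conditions."""
        return dataclasses.replace(
            self,
            promoter_dmrs={},
            n_intergenic_dmrs=0,
            marks={},
            n_extra_de=0,
        )

    @property
    def other_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.baseline_condition]


@dataclass
class Annotation:
    layout: GenomeLayout
    genes: list[GeneModel]
    cpg_positions: dict[str, np.ndarray]
    promoter_class: pd.Series  # intended low/high CpG class per gene


@dataclass
class Truth:
    """Ground truth: planted regions, classes and baselines."""

    genes: pd.DataFrame                 # baseline_log10_fpkm, silent, q, pi per window
    dmrs: pd.DataFrame                  # chrom,start,end,owner,label,condition,delta
    de: pd.DataFrame                    # gene_id, condition, log2_fold, call
    sites: pd.DataFrame | None = None   # site_id, mark, in_dmr
    prom_pi_override: dict = field(default_factory=dict)


@dataclass
class Cohort:
    config: SimulationConfig
    annotation: Annotation
    truth: Truth
    methylomes: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    sites: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig, rng: np.random.Generator) -> Annotation:
    """Toy genome: non-overlapping genes with wide flanks, plus CpG positions.

    Genes are laid down left to right with at least ``min_flank`` bp between
    spans. CpGs are uniform at ``cpg_density``; promoters of a configurable
    fraction of genes are boosted to ``high_cpg_promoter_density`` so their
    CpG content exceeds the 0.03 class threshold while the rest stay below.
    """
    names = tuple(f"chr{i + 1}" for i in range(config.n_chrom))
    layout = GenomeLayout(names, (config.chrom_length,) * config.n_chrom)
    genes: list[GeneModel] = []
    lo, hi = config.gene_length_range
    for chrom in names:
        cursor = config.min_flank
        while len(genes) < config.n_genes:
            length = int(rng.integers(lo, hi + 1))
            if cursor + length + config.min_flank > config.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{len(genes):05d}"
            if strand == "+":
                genes.append(GeneModel(gid, chrom, "+", cursor, cursor + length))
            else:
                genes.append(GeneModel(gid, chrom, "-", cursor + length, cursor))
            cursor += length + config.min_flank + int(rng.exponential(config.extra_gap_mean))
        if len(genes) >= config.n_genes:
            break
    if len(genes) < config.n_genes:
        raise MethdiffError(
            f"genome too small: placed {len(genes)} of {config.n_genes} genes"
        )

    n_high = int(round(config.high_cpg_fraction * len(genes)))
    high_idx = set(rng.choice(len(genes), size=n_high, replace=False)) if n_high else set()
    promoter_class = pd.Series(
        {g.gene_id: ("high" if i in high_idx else "low") for i, g in enumerate(genes)},
        name="cpg_class",
    )

    cpg_positions: dict[str, np.ndarray] = {}
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        n_bg = rng.poisson(length * config.cpg_density)
        pos = np.unique(rng.integers(0, length, size=n_bg)) if n_bg else np.empty(0, np.int64)
        cpg_positions[chrom] = pos.astype(np.int64)
    if config.cpg_density > 0:
        boost = max(config.high_cpg_promoter_density - config.cpg_density, 0.0)
        for i, gene in enumerate(genes):
            if i not in high_idx or boost == 0:
                continue
            prom = promoter_region(gene, layout)
            n_extra = rng.poisson(boost * len(prom))
            if n_extra:
                extra = rng.integers(prom.start, prom.end, size=n_extra)
                cpg_positions[gene.chrom] = np.unique(
                    np.concatenate([cpg_positions[gene.chrom], extra])
                ).astype(np.int64)
    total = sum(len(v) for v in cpg_positions.values())
    logger.info("generate_annotation: %d genes, %d CpGs", len(genes), total)
    return Annotation(layout, genes, cpg_positions, promoter_class)


# ---------------------------------------------------------------------------
# ground truth: baselines, planted DMRs, DE assignments
# ---------------------------------------------------------------------------

def _clip_pi(x):
    return np.clip(x, 0.02, 0.98)


def plant_truth(
    annotation: Annotation, config: SimulationConfig, rng: np.random.Generator
) -> Truth:
    """Draw gene baselines and plant the differential-methylation truth."""
    genes = annotation.genes
    ids = [g.gene_id for g in genes]
    n = len(genes)

    base_log = rng.normal(config.log10_fpkm_mean, config.log10_fpkm_sd, size=n)
    silent = rng.random(n) < config.silent_fraction
    q = np.zeros(n)
    if (~silent).sum() > 1:
        order = np.argsort(base_log[~silent], kind="stable")
        ranks = np.empty(order.size)
        ranks[order] = np.arange(order.size)
        q[~silent] = ranks / max(order.size - 1, 1)

    noise = rng.normal(0.0, config.meth_noise_sd, size=(2, n))
    prom_pi = np.empty(n)
    for i, g in enumerate(genes):
        icept, slope = (
            config.high_cpg_promoter_meth
            if annotation.promoter_class[g.gene_id] == "high"
            else config.low_cpg_promoter_meth
        )
        prom_pi[i] = icept + slope * q[i] + noise[0, i]
    body_icept, body_slope = config.gene_body_meth
    body_pi = body_icept + body_slope * q + noise[1, :]
    prom_pi = _clip_pi(prom_pi)
    body_pi = _clip_pi(body_pi)

    gene_truth = pd.DataFrame(
        {
            "baseline_log10_fpkm": np.where(silent, -np.inf, base_log),
            "silent": silent,
            "expr_quantile": q,
            "promoter_class": annotation.promoter_class.loc[ids].to_numpy(),
            "promoter_pi": prom_pi,
            "body_pi": body_pi,
        },
        index=pd.Index(ids, name="gene_id"),
    )

    # planted promoter DMRs, disjoint gene sets across condition pairs
    dmr_rows = []
    prom_override: dict[str, dict[str, float]] = {c: {} for c in config.other_conditions}
    used: set[int] = set()
    delta = config.dmr_delta
    for cond in config.other_conditions:
        n_hypo, n_hyper = config.promoter_dmrs.get(cond, (0, 0))
        for direction, count in (("hypo", n_hypo), ("hyper", n_hyper)):
            if count == 0:
                continue
            if direction == "hypo":
                eligible = [i for i in range(n) if prom_pi[i] >= delta + 0.05 and i not in used]
            else:
                eligible = [i for i in range(n) if prom_pi[i] <= 0.95 - delta and i not in used]
            if len(eligible) < count:
                raise MethdiffError(
                    f"only {len(eligible)} promoters eligible for {count} "
                    f"{direction} DMRs ({cond})"
                )
            chosen = rng.choice(eligible, size=count, replace=False)
            for i in chosen:
                used.add(int(i))
                gene = genes[i]
                shift = -delta if direction == "hypo" else delta
                prom_override[cond][gene.gene_id] = float(_clip_pi(prom_pi[i] + shift))
                prom = promoter_region(gene, annotation.layout)
                dmr_rows.append(
                    (prom.chrom, prom.start, prom.end, gene.gene_id, "promoter",
                     cond, shift, direction)
                )

    # planted intergenic hypo-DMRs just beyond gene TES ends (within 3 kb of span)
    if config.n_intergenic_dmrs:
        if config.n_intergenic_dmrs > n:
            raise MethdiffError("more intergenic DMRs requested than genes available")
        hosts = rng.choice(n, size=config.n_intergenic_dmrs, replace=False)
        for i in hosts:
            gene = genes[i]
            span_lo, span_hi = gene.span
            offset = int(rng.integers(200, 1201))
            if gene.strand == "+":
                start = span_hi + offset
            else:
                start = span_lo - offset - config.intergenic_dmr_length
            start = max(start, 0)
            end = min(start + config.intergenic_dmr_length,
                      annotation.layout.length_of(gene.chrom))
            dmr_rows.append(
                (gene.chrom, start, end, gene.gene_id, "intergenic",
                 config.intergenic_dmr_condition, -config.intergenic_dmr_delta, "hypo")
            )

    dmrs = pd.DataFrame(
        dmr_rows,
        columns=["chrom", "start", "end", "owner", "label", "condition", "delta", "direction"],
    )
    truth = Truth(genes=gene_truth, dmrs=dmrs, de=pd.DataFrame(), prom_pi_override=prom_override)
    logger.info(
        "plant_truth: %d promoter DMRs, %d intergenic DMRs",
        int((dmrs["label"] == "promoter").sum()) if len(dmrs) else 0,
        int((dmrs["label"] == "intergenic").sum()) if len(dmrs) else 0,
    )
    return truth


def assign_de(
    annotation: Annotation, truth: Truth, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Assign differential-expression truth, coupled to planted methylation.

    Genes with a planted hypomethylated promoter or a hosted hypomethylated
    intergenic DMR are activated in the corresponding condition with
    probability ``dmr_de_coupling``; hypermethylated promoters couple to
    repression. ``n_extra_de`` further genes per condition change direction
    at random, keeping the expression variation of the two comparisons at a
    similar magnitude.
    """
    ids = list(truth.genes.index)
    silent = truth.genes["silent"]
    rows = []
    assigned: dict[str, set[str]] = {c: set() for c in config.other_conditions}
    if len(truth.dmrs):
        for row in truth.dmrs.itertuples(index=False):
            cond = row.condition
            if cond not in assigned or row.owner in assigned[cond] or silent.get(row.owner, False):
                continue
            if rng.random() < config.dmr_de_coupling:
                call = "activated" if row.direction == "hypo" else "repressed"
                fold = config.de_log2_fold if call == "activated" else -config.de_log2_fold
                rows.append((row.owner, cond, fold, call))
                assigned[cond].add(row.owner)
    for cond in config.other_conditions:
        pool = [g for g in ids if g not in assigned[cond] and not silent[g]]
        count = min(config.n_extra_de, len(pool))
        for g in rng.choice(pool, size=count, replace=False) if count else []:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fold = sign * config.de_log2_fold
            call = "activated" if sign > 0 else "repressed"
            rows.append((g, cond, fold, call))
            assigned[cond].add(g)
    truth.de = pd.DataFrame(rows, columns=["gene_id", "condition", "log2_fold", "call"])
    logger.info("assign_de: %d planted DE assignments", len(truth.de))


# ---------------------------------------------------------------------------
# signal sites
# ---------------------------------------------------------------------------

def simulate_signal_sites(
    annotation: Annotation, truth: Truth, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Place each mark's sites: a fraction inside planted intergenic
    hypo-DMRs, the remainder uniform over the genome outside all planted
    DMRs. Site lengths are uniform over the mark's length range."""
    layout = annotation.layout
    dmrs = truth.dmrs
    inter = dmrs[dmrs["label"] == "intergenic"].reset_index(drop=True) if len(dmrs) else dmrs
    avoid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(dmrs):
        for chrom, sub in dmrs.groupby("chrom"):
            s = sub.sort_values("start")
            avoid[str(chrom)] = (s["start"].to_numpy(), s["end"].to_numpy())
    probs = np.asarray(layout.chrom_lengths, float)
    probs /= probs.sum()

    rows = []
    truth_rows = []
    for mark, spec in config.marks.items():
        n_in = int(round(spec.frac_in_dmr * spec.n_sites))
        if n_in > 0 and len(inter) == 0:
            raise MethdiffError(
                f"mark {mark}: frac_in_dmr > 0 but no intergenic DMRs planted"
            )
        lo, hi = spec.length_range
        for j in range(spec.n_sites):
            sid = f"{mark}_{j:05d}"
            length = int(rng.integers(lo, hi + 1))
            if j < n_in:
                host = inter.iloc[int(rng.integers(0, len(inter)))]
                dlen = int(host["end"] - host["start"])
                length = min(length, dlen)
                start = int(host["start"]) + int(rng.integers(0, dlen - length + 1))
                chrom = str(host["chrom"])
                in_dmr = True
            else:
                chrom, start = _place_outside(layout, avoid, length, probs, rng)
                in_dmr = False
            rows.append((chrom, start, start + length, mark, sid))
            truth_rows.append((sid, mark, in_dmr))
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "mark", "site_id"])
    truth.sites = pd.DataFrame(truth_rows, columns=["site_id", "mark", "in_dmr"])
    logger.info("simulate_signal_sites: %d sites across %d marks", len(sites), len(config.marks))
    return sites


def _place_outside(layout, avoid, length, probs, rng, max_tries=200):
    names = layout.chrom_names
    for _ in range(max_tries):
        ci = int(rng.choice(len(names), p=probs))
        limit = layout.chrom_lengths[ci] - length
        if limit < 0:
            continue
        start = int(rng.integers(0, limit + 1))
        starts_ends = avoid.get(names[ci])
        if starts_ends is not None:
            s, e = starts_ends
            k = np.searchsorted(e, start, side="right")
            if k < len(s) and s[k] < start + length:
                continue
        return names[ci], start
    raise MethdiffError("could not place a site outside planted DMRs")


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def simulate_methylomes(
    annotation: Annotation,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: Truth | None = None,
    sites: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Beta-binomial CpG count tables, one per condition.

    Per CpG and condition: read depth ~ Poisson(mean_coverage); the CpG's
    methylation probability is Beta-distributed around its region's mean
    with concentration ``dispersion``; the methylated count is binomial.
    Region means come from the gene/intergenic baselines, overridden by
    planted DMRs in their target condition and by mark footprints with a
    pinned level.
    """
    layout = annotation.layout
    base_pi: dict[str, np.ndarray] = {}
    tile = 1000
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        pos = annotation.cpg_positions[chrom]
        n_tiles = length // tile + 1
        tile_pi = rng.beta(*config.intergenic_meth_beta, size=n_tiles)
        base_pi[chrom] = tile_pi[pos // tile] if len(pos) else np.empty(0)

    def paint(pi_map, chrom, start, end, value):
        pos = annotation.cpg_positions[chrom]
        lo, hi = np.searchsorted(pos, (start, end))
        pi_map[chrom][lo:hi] = value

    gene_rows = truth.genes if truth is not None else None
    if gene_rows is not None:
        for gene in annotation.genes:
            row = gene_rows.loc[gene.gene_id]
            body = gene_body_region(gene, layout)
            if body is not None:
                paint(base_pi, body.chrom, body.start, body.end, row["body_pi"])
        for gene in annotation.genes:
            prom = promoter_region(gene, layout)
            paint(base_pi, prom.chrom, prom.start, prom.end,
                  gene_rows.loc[gene.gene_id, "promoter_pi"])
    if sites is not None and truth is not None and truth.sites is not None:
        pinned = {m: s.meth_level for m, s in config.marks.items() if s.meth_level is not None}
        in_dmr = dict(zip(truth.sites["site_id"], truth.sites["in_dmr"]))
        for row in sites.itertuples(index=False):
            level = pinned.get(row.mark)
            if level is not None and not in_dmr.get(row.site_id, False):
                paint(base_pi, row.chrom, row.start, row.end, level)

    methylomes: dict[str, pd.DataFrame] = {}
    for cond in config.conditions:
        pi = {c: arr.copy() for c, arr in base_pi.items()}
        if truth is not None:
            override = truth.prom_pi_override.get(cond, {})
            gene_by_id = {g.gene_id: g for g in annotation.genes}
            for gid, value in override.items():
                prom = promoter_region(gene_by_id[gid], layout)
                paint(pi, prom.chrom, prom.start, prom.end, value)
            if len(truth.dmrs):
                all_inter = truth.dmrs[truth.dmrs["label"] == "intergenic"]
                for row in all_inter.itertuples(index=False):
                    level = config.intergenic_dmr_meth
                    if row.condition == cond:
                        level = level + row.delta
                    paint(pi, row.chrom, row.start, row.end, _clip_pi(level))
        frames = []
        for chrom in layout.chrom_names:
            pos = annotation.cpg_positions[chrom]
            if len(pos) == 0:
                continue
            level = np.clip(pi[chrom], 1e-3, 1 - 1e-3)
            total = rng.poisson(config.mean_coverage, size=len(pos))
            p = rng.beta(level * config.dispersion, (1 - level) * config.dispersion)
            meth = rng.binomial(total, p)
            frames.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos, "meth": meth, "total": total}
            ))
        methylomes[cond] = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "pos", "meth", "total"])
        )
    return methylomes


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    annotation: Annotation, truth: Truth, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """FPKM matrix: log-normal baselines, planted log2-fold shifts,
    multiplicative log-scale noise; silent genes stay at exactly zero."""
    ids = list(truth.genes.index)
    base = truth.genes["baseline_log10_fpkm"].to_numpy()
    silent = truth.genes["silent"].to_numpy()
    shifts = {c: pd.Series(0.0, index=ids) for c in config.conditions}
    if len(truth.de):
        for row in truth.de.itertuples(index=False):
            shifts[row.condition][row.gene_id] = row.log2_fold * np.log10(2.0)
    out = {}
    for cond in config.conditions:
        log_f = base + shifts[cond].to_numpy() + rng.normal(0, config.expr_noise_sd, len(ids))
        fpkm = np.power(10.0, log_f)
        fpkm[silent] = 0.0
        out[cond] = fpkm
    return pd.DataFrame(out, index=pd.Index(ids, name="gene_id"))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Generate the full synthetic study: annotation, truth, counts, FPKM, sites."""
    config = config or SimulationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    annotation = generate_annotation(config, rng)
    truth = plant_truth(annotation, config, rng)
    sites = simulate_signal_sites(annotation, truth, config, rng)
    assign_de(annotation, truth, config, rng)
    methylomes = simulate_methylomes(annotation, config, rng, truth=truth, sites=sites)
    expression = simulate_expression(annotation, truth, config, rng)
    return Cohort(config, annotation, truth, methylomes, expression, sites)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Emit the cohort as the pipeline's plain-text input files plus truth tables."""
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_layout(cohort.annotation.layout, outdir / "layout.tsv")
    io.write_genes_bed(cohort.annotation.genes, outdir / "genes.bed")
    for cond, table in cohort.methylomes.items():
        io.write_methylome(table, outdir / f"methylome_{cond}.tsv")
    io.write_expression(cohort.expression, outdir / "expression.tsv")
    sites = cohort.sites
    with open(outdir / "sites.bed", "w") as handle:
        for row in sites.itertuples(index=False):
            handle.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.mark}\t{row.site_id}\n")
    if len(sites):
        from .analysis import sites_as_regions

        io.write_regions(sites_as_regions(sites), outdir / "site_regions.bed")
    cohort.truth.dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    cohort.truth.de.to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    if cohort.truth.sites is not None:
        cohort.truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
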