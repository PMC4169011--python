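# methdiff

Differential DNA methylation calling against a length-matched random-loci
null, integrated with gene expression and transcription-factor binding
sites — plus a synthetic three-condition cohort generator so the whole
pipeline runs, and is testable, without any sequencing data.

`methdiff` is aimed at epigenomics analysts who have reduced their data to
three standard layers: per-CpG bisulfite counts (whole-genome bisulfite
sequencing), an FPKM expression matrix (RNA-seq), and ChIP peak intervals
for TFs or histone marks. It answers questions of the form: *which regions
change methylation between two cell states, is that change coupled to
expression, and is it concentrated at a particular factor's binding sites?*
The bundled study design mimics an adipogenesis setting — a somatic stem
cell baseline, a reprogrammed pluripotent state, and a differentiated fat
cell — where promoter methylation is largely pre-set before differentiation
and late hypomethylation concentrates at binding sites of an adipogenic
master regulator (a PPARγ-like TF).

## The model

For a CpG with `m` methylation-supporting reads out of `t` total, the
**mC value** is `m/t` (undefined without coverage). For a region *R*
containing covered CpGs `1..n`, the **mC ratio** is the *unweighted* mean

    mC(R) = (1/n) Σᵢ mᵢ/tᵢ

Differential methylation between conditions A and B is the difference
`Δ(R) = mC_B(R) − mC_A(R)`, classified against an empirical null: Δ is
recomputed over random genomic loci whose length distribution matches the
regions under test (10 per region, ≥ 10,000), and the **fifth percentile**
(nearest-rank) of those null differences is the hypomethylation cut-off;
the 95th percentile mirrors it for hypermethylation. By construction ~5% of
null regions are called in each direction, so the calls are calibrated
without any parametric assumption on the noise.

Around that core:

- **Windows** — promoters are TSS −1000/+500 bp, gene bodies TSS +2000 bp
  to the TES (strand-aware; too-short loci excluded); promoters split into
  low/high CpG classes at a dinucleotide density of 0.03.
- **Expression** — activated/repressed calls at a 2-fold FPKM change;
  global variation as Pearson correlation of log10(FPKM+1); a decile
  analysis contrasting the FPKM of the lowest/highest 10% mC-ratio genes
  against all genes (Wilcoxon rank-sum).
- **Integration** — sites link to genes within 3,000 bp; hypomethylated
  sites per mark are tested for over/under-representation with an exact
  binomial test at a 5% occurrence probability; DE-within-DM enrichment is
  a Fisher exact test; marker genes are those linked to a hypomethylated
  site *and* activated.

## Worked example

```python
import numpy as np, pandas as pd
import methdiff as md
from methdiff.analysis import call_dm_regions

cohort = md.simulate_cohort(rng=1)          # synthetic three-condition study
layout = cohort.annotation.layout
meths  = {c: md.Methylome(t, c) for c, t in cohort.methylomes.items()}
promoters = pd.DataFrame(
    [(p.chrom, p.start, p.end, p.owner, p.label)
     for p in (md.promoter_region(g, layout) for g in cohort.annotation.genes)],
    columns=["chrom", "start", "end", "owner", "label"])

rng = np.random.default_rng(7)
for cond in ("iPSC", "FatC"):
    calls, thr = call_dm_regions(meths["ADSC"], meths[cond], promoters, layout, rng)
    print(cond, calls["call"].value_counts().to_dict())
```

prints

```
iPSC {'stable': 232, 'hypo': 41, 'hyper': 27}
FatC {'stable': 267, 'hyper': 20, 'hypo': 13}
```

i.e. reprogramming rewires promoter methylation (68 differential promoters,
most of them planted) while differentiation barely does (33, close to the
2 × 5% false-positive floor of 300 promoters) — even though expression
moves similarly in both comparisons (PCC 0.849 vs 0.868). Scoring the
signal-site sets the same way and testing representation
(`examples/04_site_enrichment.py`):

```
H3K27me3: 44/1496 hypo sites, enrichment 0.59, p_over=1.00e+00 -> under-represented
H3K4me3:  28/1488 hypo sites, enrichment 0.38, p_over=1.00e+00 -> under-represented
PPARG:   346/1994 hypo sites, enrichment 3.47, p_over=1.64e-89 -> over-represented
```

only the TF-like mark, whose sites sit in planted differentiation DMRs, is
hypomethylated beyond chance; intersecting its site-linked genes with
activation yields the marker-gene candidates
(`examples/05_marker_genes.py`).

The `examples/` directory walks through every capability; each script
builds a small input, runs one stage and explains its numbers. A thin CLI
(`methdiff simulate | windows | dmcall | de | integrate`, global `--seed`)
wraps the same functions for shell use.

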