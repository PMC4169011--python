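"""FPKM fold-change classes, global expression variation, and the
methylation-decile expression comparison.

Differential expression is a 2-fold FPKM rule: genes whose FPKM at least
doubles are "activated", genes dropping to half or less are "repressed"
(boundaries inclusive). A small pseudocount stabilises folds at zero
expression. Genes with zero FPKM in every condition of the cohort are
"excluded" throughout. Global variation between two conditions is the
Pearson correlation of log10(FPKM + 1). The decile analysis contrasts the
FPKM distribution of genes in the lowest and highest 10% of region mC ratio
against all genes by a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import DecileReport, MethdiffError

logger = logging.getLogger(__name__)

FOLD_THRESHOLD = 2.0
EPSILON_FPKM = 0.1
DECILE_FRACTION = 0.10


def classify_de(
    expr: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    fold: float = FOLD_THRESHOLD,
    epsilon: float = EPSILON_FPKM,
) -> pd.DataFrame:
    """Per-gene fold change and call between two conditions of an FPKM table.

    ``fold = (FPKM_B + eps) / (FPKM_A + eps)``; ``call`` is activated when
    fold >= threshold, repressed when fold <= 1/threshold, excluded when the
    gene has zero FPKM in *every* column of the table, else unchanged.
    Returns a DataFrame indexed by gene id with fpkm_a, fpkm_b, fold, call.
    """
    for cond in (cond_a, cond_b):
        if cond not in expr.columns:
            raise KeyError(f"condition {cond!r} not in expression table")
    if (expr[[cond_a, cond_b]].to_numpy() < 0).any():
        raise ValueError("negative FPKM values")
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    a = expr[cond_a].to_numpy(float)
    b = expr[cond_b].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (b + epsilon) / (a + epsilon)
    call = np.full(len(expr), "unchanged", dtype=object)
    call[ratio >= fold] = "activated"
    call[ratio <= 1.0 / fold] = "repressed"
    silent = (expr.to_numpy(float) == 0).all(axis=1)
    call[silent] = "excluded"
    if epsilon == 0:
        call[(a == 0) & (b == 0) & ~silent] = "unchanged"  # 0/0 fold is undefined
        ratio[(a == 0) & (b == 0)] = np.nan
    out = pd.DataFrame(
        {"fpkm_a": a, "fpkm_b": b, "fold": ratio, "call": call}, index=expr.index
    )
    logger.info(
        "classify_de(%s -> %s): %s", cond_a, cond_b, out["call"].value_counts().to_dict()
    )
    return out


def expression_pcc(
    expr: pd.DataFrame, cond_a: str, cond_b: str, exclude_silent: bool = True
) -> float:
    """Pearson correlation of log10(FPKM + 1) between two conditions.

    Genes silent in every condition of the table are dropped first. Returns
    NaN (with a warning) when either vector is constant.
    """
    sub = expr
    if exclude_silent:
        sub = expr[~(expr.to_numpy(float) == 0).all(axis=1)]
    if len(sub) < 3:
        raise MethdiffError("need at least 3 genes for a correlation")
    x = np.log10(sub[cond_a].to_numpy(float) + 1.0)
    y = np.log10(sub[cond_b].to_numpy(float) + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("expression_pcc: constant expression vector, PCC undefined")
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def decile_expression_analysis(
    mc_ratio: pd.Series,
    fpkm: pd.Series,
    fraction: float = DECILE_FRACTION,
) -> dict[str, DecileReport]:
    """Compare FPKM of the lowest/highest mC-ratio deciles against all genes.

    Both inputs are indexed by gene id; only genes present in both with a
    defined mC ratio are used. Groups are the bottom and top
    ``floor(fraction * n)`` genes after a deterministic sort by
    (mc_ratio, gene_id) — ties resolve by gene id, so membership is
    reproducible. Each group's FPKM distribution is tested against all genes
    by a two-sided Wilcoxon rank-sum test.
    """
    shared = mc_ratio.dropna().index.intersection(fpkm.index)
    if len(shared) < 10:
        raise MethdiffError(f"need at least 10 genes, got {len(shared)}")
    df = pd.DataFrame({"mc": mc_ratio.loc[shared], "fpkm": fpkm.loc[shared]})
    df = df.sort_index().sort_values("mc", kind="mergesort")  # stable: ties by gene id
    k = int(np.floor(fraction * len(df)))
    if k < 1:
        raise MethdiffError("decile groups are empty at this fraction")
    all_fpkm = df["fpkm"].to_numpy()
    low = df["fpkm"].iloc[:k].to_numpy()
    high = df["fpkm"].iloc[-k:].to_numpy()
    reports = {
        "all": DecileReport("all", len(df), float(np.median(all_fpkm))),
    }
    for name, group in (("lowest", low), ("highest", high)):
        p = float(stats.ranksums(group, all_fpkm).pvalue)
        reports[name] = DecileReport(
            f"{name}-10%-mC", k, float(np.median(group)), wilcoxon_p=p
        )
    return reports


def decile_analysis_by_class(
    mc_ratio: pd.Series,
    fpkm: pd.Series,
    cpg_class: pd.Series | None = None,
    fraction: float = DECILE_FRACTION,
) -> dict[str, dict[str, DecileReport]]:
    """Run the decile analysis pooled and (optionally) per CpG-content class."""
    out = {"pooled": decile_expression_analysis(mc_ratio, fpkm, fraction)}
    if cpg_class is not None:
        for cls in sorted(cpg_class.dropna().unique()):
            genes = cpg_class.index[cpg_class == cls]
            try:
                out[str(cls)] = decile_expression_analysis(
                    mc_ratio.reindex(genes).dropna(), fpkm, fraction
                )
            except MethdiffError as exc:
                logger.warning("decile analysis skipped for class %s: %s", cls, exc)
    return out
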