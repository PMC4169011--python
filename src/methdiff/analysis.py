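"""End-to-end convenience wrappers composing the core operations.

These are the steps the CLI and the example scripts run: build windows, call
differential methylation against the random-loci null, classify expression,
and run the site-level representation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .integrate import representation_test
from .methylome import (
    Methylome,
    call_dm,
    null_thresholds,
    random_loci_deltas,
)
from .models import GenomeLayout, NullThresholds


def call_dm_regions(
    meth_a: Methylome,
    meth_b: Methylome,
    regions: pd.DataFrame,
    layout: GenomeLayout,
    rng: np.random.Generator,
    percentile: float = 5.0,
    n_null: int | None = None,
    min_cov: int = 1,
    min_cpg: int = 1,
) -> tuple[pd.DataFrame, NullThresholds]:
    """Score regions in both conditions and classify against a fresh null.

    The null is built from random loci length-matched to ``regions`` (ten
    per region, at least 10,000). Returns the per-region call table and the
    thresholds used.
    """
    ratios_a = meth_a.region_mc_ratios(regions, min_cov=min_cov)
    ratios_b = meth_b.region_mc_ratios(regions, min_cov=min_cov)
    deltas = random_loci_deltas(
        meth_a, meth_b, regions, layout, rng, n_loci=n_null, min_cpg=min_cpg, min_cov=min_cov
    )
    thresholds = null_thresholds(deltas, percentile=percentile)
    return call_dm(ratios_a, ratios_b, thresholds), thresholds


def sites_as_regions(sites: pd.DataFrame) -> pd.DataFrame:
    """Signal-site table -> region table (owner = site id, label = mark)."""
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["start"],
            "end": sites["end"],
            "owner": sites["site_id"] if "site_id" in sites else sites.index.astype(str),
            "label": sites["mark"] if "mark" in sites else "signal_site",
        }
    )
    return out.reset_index(drop=True)


def mark_representation_tests(
    site_calls: pd.DataFrame, p0: float = 0.05, direction: str = "hypo"
) -> pd.DataFrame:
    """Per-mark binomial representation test of DM sites.

    ``site_calls`` is a call table whose ``label`` column carries the mark;
    k counts sites called in ``direction`` among the n sites with a defined
    call for that mark.
    """
    rows = []
    for mark, sub in site_calls.groupby("label", sort=True):
        defined = sub[sub["call"] != "undefined"]
        if len(defined) == 0:
            continue
        res = representation_test(
            int((defined["call"] == direction).sum()), len(defined), p0=p0, mark=str(mark)
        )
        rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows])
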