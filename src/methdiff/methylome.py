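"""Region methylation, the random-loci null, and differential calling.

The per-CpG methylation level (mC value) is the fraction of reads supporting
methylation. A region's mC ratio is the *unweighted* mean of mC values over
the covered CpGs it contains — every CpG contributes equally regardless of
its read depth. Differential methylation between two conditions is the
difference of region mC ratios, classified against percentile thresholds of
the same difference computed over random genomic loci whose length
distribution matches the regions under test: by construction roughly 5% of
null loci fall below the default hypomethylation cut-off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import regions_to_frame
from .models import (
    GenomeLayout,
    MethdiffError,
    NullThresholds,
    Region,
    RegionMethylation,
)

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 5.0
MIN_NULL_DELTAS = 20


def mc_value(meth: int, total: int, min_cov: int = 1) -> float:
    """Per-CpG methylation level, NaN when coverage is below ``min_cov``."""
    if total < min_cov or total == 0:
        return float("nan")
    return meth / total


class Methylome:
    """One condition's CpG counts with O(log n) region queries.

    Internally keeps, per chromosome, position-sorted arrays plus prefix sums
    of mC values and covered-CpG indicators, so a region's mC ratio is two
    binary searches and a subtraction.
    """

    def __init__(self, table: pd.DataFrame, condition: str = ""):
        required = {"chrom", "pos", "meth", "total"}
        if not required.issubset(table.columns):
            raise ValueError(f"methylome table needs columns {sorted(required)}")
        if (table["meth"] > table["total"]).any():
            raise ValueError("methylated count exceeds total")
        self.condition = condition
        table = table.sort_values(["chrom", "pos"], kind="mergesort")
        self._chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in table.groupby("chrom", sort=False):
            self._chrom[str(chrom)] = {
                "pos": sub["pos"].to_numpy(np.int64),
                "meth": sub["meth"].to_numpy(np.float64),
                "total": sub["total"].to_numpy(np.float64),
            }
        self._index_cache: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self.n_cpg = int(len(table))

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom)

    def _index(self, min_cov: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if min_cov not in self._index_cache:
            idx = {}
            for chrom, arrs in self._chrom.items():
                covered = arrs["total"] >= max(min_cov, 1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    mc = np.where(covered, arrs["meth"] / np.maximum(arrs["total"], 1), 0.0)
                cum_mc = np.concatenate(([0.0], np.cumsum(mc)))
                cum_n = np.concatenate(([0], np.cumsum(covered.astype(np.int64))))
                idx[chrom] = (cum_mc, cum_n)
            self._index_cache[min_cov] = idx
        return self._index_cache[min_cov]

    def covered_positions(self, min_cov: int = 1) -> dict[str, np.ndarray]:
        """Sorted positions of CpGs with coverage >= min_cov, per chromosome."""
        out = {}
        for chrom, arrs in self._chrom.items():
            out[chrom] = arrs["pos"][arrs["total"] >= max(min_cov, 1)]
        return out

    def region_mc_ratios(
        self, regions: pd.DataFrame | list[Region], min_cov: int = 1
    ) -> pd.DataFrame:
        """mC ratio and covered-CpG count for each region.

        Returns a copy of the region table with ``mc_ratio`` (NaN when the
        region holds no covered CpG) and ``n_cpg`` columns appended.
        """
        regions = regions_to_frame(regions).reset_index(drop=True)
        idx = self._index(min_cov)
        ratios = np.full(len(regions), np.nan)
        counts = np.zeros(len(regions), dtype=np.int64)
        for chrom, sub in regions.groupby("chrom", sort=False):
            chrom = str(chrom)
            if chrom not in self._chrom:
                continue
            pos = self._chrom[chrom]["pos"]
            cum_mc, cum_n = idx[chrom]
            lo = np.searchsorted(pos, sub["start"].to_numpy())
            hi = np.searchsorted(pos, sub["end"].to_numpy())
            n = cum_n[hi] - cum_n[lo]
            total_mc = cum_mc[hi] - cum_mc[lo]
            with np.errstate(invalid="ignore"):
                r = np.where(n > 0, total_mc / np.maximum(n, 1), np.nan)
            ratios[sub.index] = r
            counts[sub.index] = n
        out = regions.copy()
        out["mc_ratio"] = ratios
        out["n_cpg"] = counts
        return out

    def region_mc_ratio(self, region: Region, min_cov: int = 1) -> RegionMethylation:
        df = self.region_mc_ratios([region], min_cov=min_cov)
        return RegionMethylation(
            region=region,
            mc_ratio=float(df["mc_ratio"].iloc[0]),
            n_cpg=int(df["n_cpg"].iloc[0]),
        )


def sample_random_loci(
    templates: pd.DataFrame | list[Region] | np.ndarray,
    layout: GenomeLayout,
    cpg_index: dict[str, np.ndarray],
    rng: np.random.Generator,
    min_cpg: int = 1,
    max_tries: int = 100,
) -> pd.DataFrame:
    """Random genomic loci length-matched to a template set.

    One locus per template, with the template's exact length; chromosomes
    are chosen with probability proportional to their length and the start
    is uniform. A draw is rejected (up to ``max_tries`` times) when the
    locus does not fit on the chosen chromosome or contains fewer than
    ``min_cpg`` covered CpGs; templates still unplaced after that are
    dropped with a warning.
    """
    if isinstance(templates, (pd.DataFrame, list)):
        tdf = regions_to_frame(templates)
        lengths = (tdf["end"] - tdf["start"]).to_numpy(np.int64)
    else:
        lengths = np.asarray(templates, dtype=np.int64)
    if len(lengths) == 0:
        raise MethdiffError("no template regions to match")
    chrom_lengths = np.asarray(layout.chrom_lengths, dtype=np.float64)
    if lengths.max() > chrom_lengths.max():
        raise MethdiffError("a template is longer than every chromosome")
    probs = chrom_lengths / chrom_lengths.sum()
    names = list(layout.chrom_names)
    pos_by_chrom = {c: np.asarray(cpg_index.get(c, np.empty(0, dtype=np.int64))) for c in names}

    n = len(lengths)
    out_chrom = np.zeros(n, dtype=np.int64)
    out_start = np.zeros(n, dtype=np.int64)
    unresolved = np.ones(n, dtype=bool)
    for _ in range(max_tries):
        todo = np.flatnonzero(unresolved)
        if todo.size == 0:
            break
        ci = rng.choice(len(names), size=todo.size, p=probs)
        limits = np.asarray(layout.chrom_lengths)[ci] - lengths[todo]
        fits = limits >= 0
        starts = np.zeros(todo.size, dtype=np.int64)
        starts[fits] = rng.integers(0, limits[fits] + 1)
        ok = fits.copy()
        for k in np.flatnonzero(fits):
            pos = pos_by_chrom[names[ci[k]]]
            lo = np.searchsorted(pos, starts[k])
            hi = np.searchsorted(pos, starts[k] + lengths[todo[k]])
            if hi - lo < min_cpg:
                ok[k] = False
        placed = todo[ok]
        out_chrom[placed] = ci[ok]
        out_start[placed] = starts[ok]
        unresolved[placed] = False
    if unresolved.all():
        raise MethdiffError(
            "could not place any random locus; is the genome devoid of covered CpGs?"
        )
    if unresolved.any():
        logger.warning("sample_random_loci: dropped %d of %d templates", int(unresolved.sum()), n)
    keep = ~unresolved
    return pd.DataFrame(
        {
            "chrom": [names[i] for i in out_chrom[keep]],
            "start": out_start[keep],
            "end": out_start[keep] + lengths[keep],
            "owner": [f"template_{i}" for i in np.flatnonzero(keep)],
            "label": "random_locus",
        }
    )


def random_loci_deltas(
    meth_a: Methylome,
    meth_b: Methylome,
    templates: pd.DataFrame | list[Region],
    layout: GenomeLayout,
    rng: np.random.Generator,
    n_loci: int | None = None,
    min_cpg: int = 1,
    min_cov: int = 1,
) -> np.ndarray:
    """Null distribution of mC-ratio differences (B - A) over random loci.

    Template lengths are tiled up to ``n_loci`` draws (default
    ``max(10 * n_templates, 10000)`` for a stable fifth-percentile tail).
    Loci must contain a covered CpG in both conditions; undefined deltas are
    dropped.
    """
    tdf = regions_to_frame(templates)
    lengths = (tdf["end"] - tdf["start"]).to_numpy(np.int64)
    if n_loci is None:
        n_loci = max(10 * len(lengths), 10_000)
    reps = int(math.ceil(n_loci / len(lengths)))
    tiled = np.tile(lengths, reps)[:n_loci]
    cpg_index = _joint_covered(meth_a, meth_b, min_cov)
    loci = sample_random_loci(tiled, layout, cpg_index, rng, min_cpg=min_cpg)
    ra = meth_a.region_mc_ratios(loci, min_cov=min_cov)["mc_ratio"].to_numpy()
    rb = meth_b.region_mc_ratios(loci, min_cov=min_cov)["mc_ratio"].to_numpy()
    deltas = rb - ra
    return deltas[~np.isnan(deltas)]


def _joint_covered(meth_a: Methylome, meth_b: Methylome, min_cov: int) -> dict[str, np.ndarray]:
    """Positions covered in both conditions, so null loci are scorable in each."""
    a = meth_a.covered_positions(min_cov)
    b = meth_b.covered_positions(min_cov)
    return {
        chrom: np.intersect1d(a[chrom], b[chrom], assume_unique=True)
        for chrom in set(a) & set(b)
    }


def null_thresholds(
    deltas: np.ndarray, percentile: float = DEFAULT_PERCENTILE
) -> NullThresholds:
    """Nearest-rank percentile cut-offs of the null delta distribution.

    ``hypo_cut`` is the ``percentile``-th nearest-rank value, ``hyper_cut``
    the ``100 - percentile``-th; no interpolation is applied, so thresholds
    are reproducible across numeric stacks.
    """
    deltas = np.asarray(deltas, dtype=float)
    deltas = deltas[~np.isnan(deltas)]
    if len(deltas) < MIN_NULL_DELTAS:
        raise MethdiffError(
            f"need at least {MIN_NULL_DELTAS} defined null deltas, got {len(deltas)}"
        )
    if not 0 < percentile < 50:
        raise ValueError("percentile must lie in (0, 50)")
    s = np.sort(deltas)
    return NullThresholds(
        hypo_cut=float(_nearest_rank(s, percentile)),
        hyper_cut=float(_nearest_rank(s, 100.0 - percentile)),
        n_null=len(s),
        percentile=percentile,
    )


def _nearest_rank(sorted_values: np.ndarray, p: float) -> float:
    n = len(sorted_values)
    rank = max(int(math.ceil(p / 100.0 * n)), 1)
    return sorted_values[rank - 1]


def call_dm(
    ratios_a: pd.DataFrame, ratios_b: pd.DataFrame, thresholds: NullThresholds
) -> pd.DataFrame:
    """Classify matched regions as hypo / hyper / stable / undefined.

    ``delta = mc_ratio(B) - mc_ratio(A)``; deltas at or below the hypo cut
    are hypomethylated, at or above the hyper cut hypermethylated (a delta
    hitting a degenerate shared cut counts as hypo). Regions undefined in
    either condition propagate as ``undefined``.
    """
    for col in ("chrom", "start", "end", "mc_ratio"):
        if col not in ratios_a.columns or col not in ratios_b.columns:
            raise ValueError(f"ratio tables need column {col!r}")
    a = ratios_a.reset_index(drop=True)
    b = ratios_b.reset_index(drop=True)
    if len(a) != len(b) or not (
        a[["chrom", "start", "end"]].equals(b[["chrom", "start", "end"]])
    ):
        raise MethdiffError("region sets are not matched one-to-one")
    delta = b["mc_ratio"].to_numpy() - a["mc_ratio"].to_numpy()
    call = np.full(len(a), "stable", dtype=object)
    call[delta <= thresholds.hypo_cut] = "hypo"
    call[(delta >= thresholds.hyper_cut) & (call != "hypo")] = "hyper"
    call[np.isnan(delta)] = "undefined"
    out = a.copy()
    out = out.rename(columns={"mc_ratio": "mc_a", "n_cpg": "n_cpg_a"})
    out["mc_b"] = b["mc_ratio"].to_numpy()
    if "n_cpg" in b.columns:
        out["n_cpg_b"] = b["n_cpg"].to_numpy()
    out["delta"] = delta
    out["call"] = call
    counts = pd.Series(call).value_counts().to_dict()
    logger.info("call_dm: %d regions -> %s", len(out), counts)
    return out


@dataclass(frozen=True)
class SiteProfile:
    """mC-ratio histograms at signal sites vs length-matched random loci."""

    bin_edges: np.ndarray
    site_hist: np.ndarray       # fraction of sites per bin
    random_hist: np.ndarray     # fraction of random loci per bin
    median_shift: float         # median(sites) - median(random loci)
    n_sites: int
    n_random: int


def site_methylation_profile(
    sites: pd.DataFrame | list,
    methylome: Methylome,
    layout: GenomeLayout,
    rng: np.random.Generator,
    bin_width: float = 0.05,
    min_cov: int = 1,
    min_cpg: int = 1,
    random_multiple: int = 1,
) -> SiteProfile:
    """Compare site methylation with the genomic background.

    Histograms (bin width 0.05 on [0, 1]) of region mC ratios at the sites
    and at random loci drawn with the same length distribution, plus the
    difference in medians as a single location-shift summary.
    """
    from .models import SignalSite

    if isinstance(sites, list) and sites and isinstance(sites[0], SignalSite):
        sites = pd.DataFrame(
            [(s.chrom, s.start, s.end, s.site_id or s.mark, "signal_site") for s in sites],
            columns=["chrom", "start", "end", "owner", "label"],
        )
    else:
        sites = regions_to_frame(sites)
    if len(sites) == 0:
        raise MethdiffError("empty site set")
    site_ratios = methylome.region_mc_ratios(sites, min_cov=min_cov)["mc_ratio"].to_numpy()
    site_ratios = site_ratios[~np.isnan(site_ratios)]
    lengths = np.tile((sites["end"] - sites["start"]).to_numpy(np.int64), random_multiple)
    loci = sample_random_loci(
        lengths, layout, methylome.covered_positions(min_cov), rng, min_cpg=min_cpg
    )
    rand_ratios = methylome.region_mc_ratios(loci, min_cov=min_cov)["mc_ratio"].to_numpy()
    rand_ratios = rand_ratios[~np.isnan(rand_ratios)]
    if len(site_ratios) == 0 or len(rand_ratios) == 0:
        raise MethdiffError("no defined mC ratios for sites or random loci")
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    sh, _ = np.histogram(site_ratios, bins=edges)
    rh, _ = np.histogram(rand_ratios, bins=edges)
    return SiteProfile(
        bin_edges=edges,
        site_hist=sh / sh.sum(),
        random_hist=rh / rh.sum(),
        median_shift=float(np.median(site_ratios) - np.median(rand_ratios)),
        n_sites=int(len(site_ratios)),
        n_random=int(len(rand_ratios)),
    )
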