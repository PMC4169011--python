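import math

import numpy as np
import pandas as pd
import pytest

from methdiff.methylome import (
    Methylome,
    call_dm,
    mc_value,
    null_thresholds,
    sample_random_loci,
    site_methylation_profile,
)
from methdiff.models import GenomeLayout, MethdiffError, NullThresholds, Region


def make_methylome(rows, condition=""):
    return Methylome(
        pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"]), condition
    )


def region_frame(triples):
    return pd.DataFrame(
        [(c, s, e, f"r{i}", "region") for i, (c, s, e) in enumerate(triples)],
        columns=["chrom", "start", "end", "owner", "label"],
    )


class TestMcValue:
    @pytest.mark.parametrize(
        "meth,total,expected", [(7, 10, 0.7), (0, 12, 0.0), (10, 10, 1.0)]
    )
    def test_fraction(self, meth, total, expected):
        assert mc_value(meth, total) == pytest.approx(expected)

    def test_no_coverage_is_undefined(self):
        assert math.isnan(mc_value(0, 0))

    def test_min_cov_filter(self):
        assert math.isnan(mc_value(2, 3, min_cov=5))


class TestRegionMcRatio:
    def test_unweighted_mean(self):
        m = make_methylome(
            [("chr1", 10, 2, 10), ("chr1", 20, 4, 10), ("chr1", 30, 6, 10)]
        )
        rm = m.region_mc_ratio(Region("chr1", 0, 100))
        assert rm.mc_ratio == pytest.approx(0.4)
        assert rm.n_cpg == 3

    def test_no_cpgs_is_undefined(self):
        m = make_methylome([("chr1", 500, 2, 10)])
        rm = m.region_mc_ratio(Region("chr1", 0, 100))
        assert math.isnan(rm.mc_ratio) and rm.n_cpg == 0

    def test_mean_is_not_coverage_weighted(self):
        # 0.5 at depth 10 and 1.0 at depth 1: unweighted 0.75, weighted 0.545
        m = make_methylome([("chr1", 10, 5, 10), ("chr1", 20, 1, 1)])
        rm = m.region_mc_ratio(Region("chr1", 0, 100))
        assert rm.mc_ratio == pytest.approx(0.75)

    def test_zero_coverage_cpgs_excluded(self):
        m = make_methylome([("chr1", 10, 0, 0), ("chr1", 20, 5, 10)])
        rm = m.region_mc_ratio(Region("chr1", 0, 100))
        assert rm.mc_ratio == pytest.approx(0.5) and rm.n_cpg == 1

    def test_matches_per_cpg_loop_oracle(self):
        """Vectorised region means agree with a brute-force loop on 1,000
        random regions."""
        rng = np.random.default_rng(42)
        n_cpg = 4000
        pos = np.sort(rng.choice(100_000, size=n_cpg, replace=False))
        total = rng.poisson(8, n_cpg)
        meth = rng.binomial(total, rng.random(n_cpg))
        table = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "meth": meth, "total": total}
        )
        m = Methylome(table)
        starts = rng.integers(0, 99_000, size=1000)
        ends = starts + rng.integers(1, 3000, size=1000)
        regions = region_frame([("chr1", s, e) for s, e in zip(starts, ends)])
        got = m.region_mc_ratios(regions)
        lookup = {p: (mm, t) for p, mm, t in zip(pos, meth, total)}
        for row in got.itertuples(index=False):
            values = [
                mm / t
                for p, (mm, t) in lookup.items()
                if row.start <= p < row.end and t >= 1
            ]
            if values:
                assert row.mc_ratio == pytest.approx(np.mean(values), abs=1e-12)
                assert row.n_cpg == len(values)
            else:
                assert math.isnan(row.mc_ratio) and row.n_cpg == 0

    def test_min_cov_monotonicity(self):
        rng = np.random.default_rng(0)
        total = rng.poisson(5, 500)
        table = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(500) * 10,
                "meth": rng.binomial(total, 0.3),
                "total": total,
            }
        )
        m = Methylome(table)
        regions = region_frame([("chr1", i * 250, i * 250 + 400) for i in range(15)])
        previous = None
        for min_cov in (1, 3, 6, 10):
            n = m.region_mc_ratios(regions, min_cov=min_cov)["n_cpg"].to_numpy()
            if previous is not None:
                assert (n <= previous).all()
            previous = n


class TestSampleRandomLoci:
    layout = GenomeLayout(("chr1", "chr2"), (50_000, 30_000))

    def cpg_index(self):
        return {
            "chr1": np.arange(0, 50_000, 40),
            "chr2": np.arange(0, 30_000, 40),
        }

    def test_length_distribution_preserved(self):
        templates = region_frame(
            [("chr1", 0, 500), ("chr1", 1000, 2500), ("chr2", 0, 500)]
        )
        loci = sample_random_loci(
            templates, self.layout, self.cpg_index(), np.random.default_rng(1)
        )
        assert sorted(loci["end"] - loci["start"]) == [500, 500, 1500]

    def test_fixed_seed_reproducible(self):
        templates = region_frame([("chr1", 0, 800)] * 20)
        a = sample_random_loci(
            templates, self.layout, self.cpg_index(), np.random.default_rng(9)
        )
        b = sample_random_loci(
            templates, self.layout, self.cpg_index(), np.random.default_rng(9)
        )
        pd.testing.assert_frame_equal(a, b)

    def test_no_cpgs_anywhere_raises(self):
        templates = region_frame([("chr1", 0, 500)])
        empty = {"chr1": np.empty(0, int), "chr2": np.empty(0, int)}
        with pytest.raises(MethdiffError):
            sample_random_loci(
                templates, self.layout, empty, np.random.default_rng(1)
            )

    def test_min_cpg_respected(self):
        index = {"chr1": np.arange(0, 50_000, 100), "chr2": np.empty(0, int)}
        loci = sample_random_loci(
            np.full(50, 1000),
            self.layout,
            index,
            np.random.default_rng(3),
            min_cpg=5,
        )
        for row in loci.itertuples(index=False):
            n = np.searchsorted(index[row.chrom], row.end) - np.searchsorted(
                index[row.chrom], row.start
            )
            assert n >= 5


class TestNullThresholds:
    def test_nearest_rank_matches_sorting_oracle(self):
        rng = np.random.default_rng(5)
        for n in (20, 99, 100, 101, 1234):
            deltas = rng.normal(0, 0.1, n)
            thr = null_thresholds(deltas, percentile=5)
            s = np.sort(deltas)
            assert thr.hypo_cut == s[max(math.ceil(0.05 * n), 1) - 1]
            assert thr.hyper_cut == s[max(math.ceil(0.95 * n), 1) - 1]

    def test_symmetric_grid_fifth_smallest(self):
        deltas = np.linspace(-0.10, 0.10, 100)
        thr = null_thresholds(deltas, percentile=5)
        assert thr.hypo_cut == np.sort(deltas)[4]

    def test_degenerate_all_zero(self):
        thr = null_thresholds(np.zeros(100))
        assert thr.hypo_cut == 0 and thr.hyper_cut == 0

    def test_median_at_fifty(self):
        deltas = np.arange(101) / 100 - 0.5
        thr = null_thresholds(deltas, percentile=49.999)
        assert thr.hypo_cut == pytest.approx(0.0, abs=0.011)

    def test_too_few_deltas_raises(self):
        with pytest.raises(MethdiffError):
            null_thresholds(np.zeros(19))


class TestCallDm:
    thresholds = NullThresholds(hypo_cut=-0.1, hyper_cut=0.1, n_null=100)

    def ratio_frames(self, values_a, values_b):
        base = region_frame([("chr1", i * 100, i * 100 + 50) for i in range(len(values_a))])
        a = base.assign(mc_ratio=values_a, n_cpg=5)
        b = base.assign(mc_ratio=values_b, n_cpg=5)
        return a, b

    def test_classification(self):
        a, b = self.ratio_frames([0.8, 0.5, 0.2, 0.5], [0.3, 0.5, 0.7, np.nan])
        calls = call_dm(a, b, self.thresholds)
        assert list(calls["call"]) == ["hypo", "stable", "hyper", "undefined"]

    def test_unmatched_regions_rejected(self):
        a, b = self.ratio_frames([0.5], [0.5])
        b = b.assign(start=b["start"] + 1)
        with pytest.raises(MethdiffError):
            call_dm(a, b, self.thresholds)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(2)
        va, vb = rng.random(200), rng.random(200)
        a, b = self.ratio_frames(va, vb)
        fwd = call_dm(a, b, self.thresholds)
        swapped = NullThresholds(
            hypo_cut=-self.thresholds.hyper_cut, hyper_cut=-self.thresholds.hypo_cut,
            n_null=100,
        )
        rev = call_dm(b, a, swapped)
        assert set(fwd.loc[fwd["call"] == "hypo", "owner"]) == set(
            rev.loc[rev["call"] == "hyper", "owner"]
        )
        assert set(fwd.loc[fwd["call"] == "hyper", "owner"]) == set(
            rev.loc[rev["call"] == "hypo", "owner"]
        )


class TestSiteProfile:
    layout = GenomeLayout(("chr1",), (100_000,))

    def test_fully_methylated_sites_in_top_bin(self):
        table = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(0, 100_000, 50),
             "meth": 10, "total": 10}
        )
        m = Methylome(table)
        sites = region_frame([("chr1", i * 2000, i * 2000 + 500) for i in range(20)])
        profile = site_methylation_profile(
            sites, m, self.layout, np.random.default_rng(1)
        )
        assert profile.site_hist[-1] == pytest.approx(1.0)
        assert profile.median_shift == pytest.approx(0.0)

    def test_hypomethylated_sites_shift_negative(self):
        pos = np.arange(0, 100_000, 50)
        meth = np.full(len(pos), 9)
        low = (pos // 2000) % 4 == 0  # every fourth 2-kb block unmethylated
        meth[low] = 1
        m = Methylome(
            pd.DataFrame({"chrom": "chr1", "pos": pos, "meth": meth, "total": 10})
        )
        sites = region_frame(
            [("chr1", i * 8000 + 100, i * 8000 + 1900) for i in range(12)]
        )
        profile = site_methylation_profile(
            sites, m, self.layout, np.random.default_rng(1), random_multiple=20
        )
        assert profile.median_shift < -0.3

    def test_empty_site_set_raises(self):
        m = make_methylome([("chr1", 10, 1, 2)])
        with pytest.raises(MethdiffError):
            site_methylation_profile(
                region_frame([]), m, self.layout, np.random.default_rng(1)
            )
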