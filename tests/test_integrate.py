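import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from methdiff.integrate import (
    associate_sites,
    de_dm_enrichment,
    enrichment_grid,
    representation_test,
    select_marker_genes,
)
from methdiff.models import GeneModel, MethdiffError


def binom_tail_oracle(k, n, p, upper):
    """Brute-force binomial tail by summing pmf terms with math.comb."""
    ks = range(k, n + 1) if upper else range(0, k + 1)
    return float(sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in ks))


def fisher_oracle(a, b, c, d):
    """Exact one-sided hypergeometric tails by enumeration, in Fractions."""
    row1, col1, total = a + b, a + c, a + b + c + d

    def pmf(x):
        return (
            Fraction(math.comb(col1, x))
            * Fraction(math.comb(total - col1, row1 - x))
            / Fraction(math.comb(total, row1))
        )

    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    greater = sum(pmf(x) for x in range(a, hi + 1))
    less = sum(pmf(x) for x in range(lo, a + 1))
    return float(greater), float(less)


class TestAssociateSites:
    genes = [GeneModel("gA", "chr1", "+", 10_000, 20_000)]

    def sites(self, start, end):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [start], "end": [end], "site_id": ["s1"]}
        )

    def test_upstream_within_3kb_linked(self):
        links = associate_sites(self.sites(7_000, 7_500), self.genes)
        assert list(links["gene_id"]) == ["gA"]
        assert links["distance"].iloc[0] == 2_500

    def test_beyond_3kb_not_linked(self):
        assert len(associate_sites(self.sites(23_500, 24_000), self.genes)) == 0

    def test_overlap_distance_zero(self):
        links = associate_sites(self.sites(15_000, 15_200), self.genes)
        assert links["distance"].iloc[0] == 0

    def test_boundary_exactly_3kb_linked(self):
        links = associate_sites(self.sites(23_000, 23_400), self.genes)
        assert links["distance"].iloc[0] == 3_000

    def test_tss_anchor(self):
        # inside the gene body: distance 0 to the span but 999 to the TSS point
        span_links = associate_sites(self.sites(11_000, 11_200), self.genes)
        tss_links = associate_sites(self.sites(11_000, 11_200), self.genes, anchor="tss")
        assert span_links["distance"].iloc[0] == 0
        assert tss_links["distance"].iloc[0] == 999

    def test_many_to_many(self):
        genes = self.genes + [GeneModel("gB", "chr1", "-", 26_000, 21_000)]
        links = associate_sites(self.sites(20_200, 20_400), genes)
        assert set(links["gene_id"]) == {"gA", "gB"}


class TestRepresentationTest:
    @pytest.mark.parametrize(
        "k,n,p0",
        [(0, 50, 0.05), (3, 50, 0.05), (12, 200, 0.05), (40, 200, 0.2),
         (5, 1000, 0.01), (995, 1000, 0.99), (77, 1000, 0.05)],
    )
    def test_matches_pmf_sum_oracle(self, k, n, p0):
        res = representation_test(k, n, p0)
        assert res.p_over == pytest.approx(binom_tail_oracle(k, n, p0, True), rel=1e-12)
        assert res.p_under == pytest.approx(binom_tail_oracle(k, n, p0, False), rel=1e-12)

    def test_expectation_gives_unit_enrichment(self):
        assert representation_test(5, 100, 0.05).enrichment == pytest.approx(1.0)

    def test_zero_hits_under_tail_closed_form(self):
        res = representation_test(0, 100, 0.05)
        assert res.p_under == pytest.approx(0.95**100, rel=1e-12)

    def test_empty_site_set_rejected(self):
        with pytest.raises(MethdiffError):
            representation_test(0, 0)


class TestDeDmEnrichment:
    @staticmethod
    def build_sets(a, b, c, d):
        universe = {f"g{i}" for i in range(a + b + c + d)}
        ordered = sorted(universe)
        dm = set(ordered[: a + b])
        de = set(ordered[:a]) | set(ordered[a + b : a + b + c])
        return dm, de, universe

    def test_known_table(self):
        dm, de, universe = self.build_sets(20, 10, 10, 60)
        res = de_dm_enrichment(dm, de, universe)
        assert res.table == ((20, 10), (10, 60))
        assert res.odds_ratio == pytest.approx(12.0)
        assert res.p_enrichment < 1e-4

    @pytest.mark.parametrize(
        "table", [(5, 15, 10, 70), (20, 10, 10, 60), (1, 40, 50, 100), (8, 2, 3, 7)]
    )
    def test_matches_hypergeometric_enumeration(self, table):
        dm, de, universe = self.build_sets(*table)
        res = de_dm_enrichment(dm, de, universe)
        greater, less = fisher_oracle(*table)
        assert res.p_enrichment == pytest.approx(greater, rel=1e-9)
        assert res.p_depletion == pytest.approx(less, rel=1e-9)

    def test_dm_equals_universe_degenerate(self):
        universe = {f"g{i}" for i in range(30)}
        res = de_dm_enrichment(universe, set(list(universe)[:10]), universe)
        assert math.isinf(res.odds_ratio)
        assert res.p_depletion == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(MethdiffError):
            de_dm_enrichment(set(), set(), set())


class TestEnrichmentGrid:
    @staticmethod
    def random_ratios(n, rng):
        ids = [f"g{i}" for i in range(n)]
        return (
            pd.Series(rng.random(n), index=ids),
            pd.Series(rng.random(n), index=ids),
        )

    def test_class_equals_background_is_flat(self):
        mc_a, mc_b = self.random_ratios(2000, np.random.default_rng(1))
        grid = enrichment_grid(mc_a, mc_b, set(mc_a.index))
        unmasked = grid.enrichment[~grid.mask]
        assert np.allclose(unmasked, 1.0)

    def test_background_weighted_mean_is_one(self):
        rng = np.random.default_rng(2)
        mc_a, mc_b = self.random_ratios(3000, rng)
        class_genes = set(rng.choice(mc_a.index, 400, replace=False))
        grid = enrichment_grid(mc_a, mc_b, class_genes)
        bg = grid.bg_counts.copy()
        bg[grid.mask] = 0
        weights = bg / bg.sum()
        total = np.nansum(grid.enrichment * weights)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_corner_has_peak(self):
        rng = np.random.default_rng(3)
        mc_a, mc_b = self.random_ratios(3000, rng)
        corner = mc_a.index[(mc_a > 0.7) & (mc_b < 0.3)]
        grid = enrichment_grid(mc_a, mc_b, set(corner))
        peak_a, peak_b = grid.peak_bin()
        assert peak_a > 0.7 and peak_b < 0.3

    def test_single_bin_normalises_to_one(self):
        mc_a, mc_b = self.random_ratios(100, np.random.default_rng(4))
        grid = enrichment_grid(mc_a, mc_b, set(mc_a.index[:10]), bin_width=1.0)
        assert grid.enrichment.shape == (1, 1)
        assert grid.enrichment[0, 0] == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        mc_a, mc_b = self.random_ratios(100, np.random.default_rng(5))
        with pytest.raises(MethdiffError):
            enrichment_grid(mc_a, mc_b, set())


class TestMarkerSelection:
    site_calls = pd.DataFrame(
        {"site_id": ["s1", "s2", "s3"], "call": ["hypo", "stable", "hypo"]}
    )
    links = pd.DataFrame(
        {"site_id": ["s1", "s2", "s3"], "gene_id": ["gA", "gB", "gC"],
         "distance": [0, 100, 2000]}
    )
    de = pd.DataFrame(
        {"call": ["activated", "activated", "unchanged"]},
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )

    def test_hypo_site_and_activation_selects(self):
        assert select_marker_genes(self.site_calls, self.links, self.de) == ["gA"]

    def test_stable_site_not_selected(self):
        # gB is activated but its only site is methylation-stable
        markers = select_marker_genes(self.site_calls, self.links, self.de)
        assert "gB" not in markers

    def test_unlinked_activated_gene_not_selected(self):
        de = self.de.copy()
        de.loc["gD"] = "activated"  # no site within reach
        assert "gD" not in select_marker_genes(self.site_calls, self.links, de)
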