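import numpy as np
import pandas as pd
import pytest

import methdiff as md
from methdiff import analysis


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study, generated once per session."""
    return md.simulate_cohort(rng=1)


@pytest.fixture(scope="session")
def default_methylomes(default_cohort):
    return {c: md.Methylome(t, c) for c, t in default_cohort.methylomes.items()}


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast unit tests."""
    return md.SimulationConfig(
        n_chrom=1,
        chrom_length=900_000,
        n_genes=60,
        promoter_dmrs={"iPSC": (8, 4), "FatC": (2, 1)},
        n_intergenic_dmrs=12,
        marks={"PPARG": md.MarkSpec(300, frac_in_dmr=0.2)},
        n_extra_de=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return md.simulate_cohort(small_config, rng=11)


def promoter_table(cohort):
    rows = [md.promoter_region(g, cohort.annotation.layout) for g in cohort.annotation.genes]
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.owner, r.label) for r in rows],
        columns=["chrom", "start", "end", "owner", "label"],
    )


@pytest.fixture(scope="session")
def default_promoters(default_cohort):
    return promoter_table(default_cohort)


@pytest.fixture(scope="session")
def default_dm_calls(default_cohort, default_methylomes, default_promoters):
    """Promoter DM calls for both condition pairs plus site calls (FatC pair)."""
    layout = default_cohort.annotation.layout
    rng = np.random.default_rng(7)
    out = {}
    for cond in ("iPSC", "FatC"):
        out[cond] = analysis.call_dm_regions(
            default_methylomes["ADSC"], default_methylomes[cond],
            default_promoters, layout, rng,
        )
    sites = analysis.sites_as_regions(default_cohort.sites)
    out["sites"] = analysis.call_dm_regions(
        default_methylomes["ADSC"], default_methylomes["FatC"], sites, layout, rng
    )
    return out
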