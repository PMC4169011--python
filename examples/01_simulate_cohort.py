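"""Generate the synthetic three-condition study and look at its ground truth.

The cohort mimics a somatic stem cell (ADSC-like baseline), a reprogrammed
pluripotent derivative (iPSC-like, many planted promoter DMRs) and a
differentiated cell (FatC-like, few promoter DMRs but planted intergenic
hypomethylation hosting TF binding sites).
"""

import methdiff as md

cohort = md.simulate_cohort(rng=1)

n_cpg = sum(len(v) for v in cohort.annotation.cpg_positions.values())
print(f"genome: {cohort.annotation.layout.as_dict()}")
print(f"genes: {len(cohort.annotation.genes)}, CpGs: {n_cpg}")
for cond, table in cohort.methylomes.items():
    mean_cov = table["total"].mean()
    print(f"  {cond}: {len(table)} CpG records, mean coverage {mean_cov:.1f}x")
print("planted DMRs by type:", cohort.truth.dmrs["label"].value_counts().to_dict())
print("planted DE by condition:", cohort.truth.de["condition"].value_counts().to_dict())
print("signal sites per mark:", cohort.sites["mark"].value_counts().to_dict())

# The DMR table is the ground truth downstream calls are scored against:
# each row is a region whose methylation was shifted by `delta` in exactly
# one condition relative to the shared baseline.
print(cohort.truth.dmrs.head(3).to_string(index=False))
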