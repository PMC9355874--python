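"""LD-clump simulated GWAS summary statistics and vote on target genes.

Simulates eight LD blocks each carrying one causal variant, applies the
genome-wide eligibility screen (p < 5e-8, imputation quality > 0.6,
MAF > 1%), clumps at r² < 0.05, and runs the seven-channel evidence vote on
a small hand-built candidate-gene table for the first locus.
"""

import pandas as pd

from chforge.gwas import (
    EVIDENCE_CHANNELS,
    bonferroni_threshold,
    ld_clump,
    loci_table,
    prioritize_genes,
    significance_filter,
)
from chforge.simulate import LDSimConfig, simulate_gwas_sumstats

rows, ld = simulate_gwas_sumstats(LDSimConfig(n_blocks=8, seed=7))
eligible = significance_filter(rows, mode="common")
loci = ld_clump(eligible, ld, p_threshold=5e-8, r2_threshold=0.05)
print(f"{len(rows)} variants, {len(eligible)} eligible, {len(loci)} loci:")
print(loci_table(loci).to_string(index=False))
print(f"\ngene-level Bonferroni threshold for 19,064 genes: "
      f"{bonferroni_threshold(19_064):.2e}")

evidence = pd.DataFrame([
    {"locus": "locus_01", "gene": g,
     **{ch: v for ch, v in zip(EVIDENCE_CHANNELS, votes)}}
    for g, votes in [
        ("TERT", (1, 1, 1, 0, 1, 0, 0)),
        ("CLPTM1L", (0, 1, 0, 0, 0, 0, 0)),
        ("SLC6A18", (0, 0, 0, 0, 0, 0, 0)),
    ]
]).astype({ch: bool for ch in EVIDENCE_CHANNELS})
ranked = prioritize_genes(evidence)
print(f"\nprioritized genes at locus_01: {ranked['locus_01']}")
# One lead per simulated block (by construction); TERT wins the vote with
# four of seven channels, CLPTM1L's single nomination is below threshold.
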