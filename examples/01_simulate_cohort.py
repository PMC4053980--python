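"""Generate a synthetic multi-omic fibroblast-style cohort with ground truth.

The generator emulates a cohort of 62 individuals typed for SNP dosages
(Hardy-Weinberg, blockwise LD), CpG beta values (bimodal, with planted
cis-mQTL effects), gene expression on a 58-sample subset (planted eQTLs and
signed methylation couplings), and per-SNP allelic log2 ratios with planted
allelic-expression regions.
"""

import numpy as np

from cistriad import SimConfig, simulate_cohort

config = SimConfig(seed=1)
cohort = simulate_cohort(config)

print(f"samples: {cohort.samples.n} "
      f"(expression on {int(cohort.expression.samples.mask('expression').sum())})")
print(f"genes: {len(cohort.genes)}, CpGs: {len(cohort.cpgs)}, "
      f"SNPs: {len(cohort.snps)}")
mean_beta = cohort.methylation.beta.mean(axis=1)
print(f"hypomethylated CpGs (mean beta < 0.3): {(mean_beta < 0.3).mean():.0%}")
print(f"hypermethylated CpGs (mean beta > 0.7): {(mean_beta > 0.7).mean():.0%}")
kinds = {}
for effect in cohort.effects:
    kinds[effect.kind] = kinds.get(effect.kind, 0) + 1
print(f"planted effects: {kinds}")
print(f"planted allelic-expression regions: {len(cohort.ae_regions_truth)}")
het = np.isfinite(cohort.ae_track.raw_ratio)
print(f"heterozygous (informative) allelic entries: {het.mean():.0%}")
# The hypo/hyper split shows the bimodal beta landscape the 450K-style
# simulation reproduces; the planted-effect counts are the ground truth the
# mapping stages are expected to recover.
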