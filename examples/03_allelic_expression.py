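"""Smooth allelic ratios, calibrate the aeSNP threshold, build aeRegions.

Raw per-SNP allelic log2 ratios (defined at heterozygous SNPs) are smoothed
with an eight-state left-to-right HMM along each sample's chain of
informative SNPs. The aeSNP threshold is calibrated to a 5% false discovery
rate by permuting raw ratios within each sample, re-smoothing, and comparing
null to observed call counts; consecutive same-sign aeSNPs form aeRegions.
"""

import numpy as np

from cistriad import SimConfig, run_ae_pipeline, simulate_cohort

config = SimConfig(seed=3, n_snps=1_000, n_ae_regions=50,
                   chrom_length_bp=10_000_000, n_genes=20, n_cpgs=50,
                   n_mqtl=0, n_eqtl=0, n_methexpr=0, n_joint=0)
cohort = simulate_cohort(config)

result = run_ae_pipeline(cohort.ae_track, target_fdr=0.05, min_samples=2,
                         n_permutations=10, seed=4)
cal = result.calibration
print(f"calibrated aeSNP threshold: {cal.threshold} "
      f"(grid 0.05-1.00, target FDR 5%)")
n_called = int(result.calls["called"].sum())
print(f"aeSNPs called: {n_called} of {len(result.calls)}")
print(f"aeRegions (>= 2 consecutive same-sign aeSNPs): {len(result.regions)}")

truth = set()
for region in cohort.ae_regions_truth:
    truth |= set(region.snp_indices)
called = set(np.flatnonzero(result.calls["called"].to_numpy()))
print(f"planted member SNPs recovered: {len(called & truth)}/{len(truth)}")
print(f"calls outside planted regions: {len(called - truth)}")
# The threshold typically lands at the 0.2-0.25 scale; calls outside planted
# regions are mostly flanking SNPs the smoother drags along region borders.
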