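"""Classify CpG context and count modes of each probe's beta distribution.

Probes are labelled by position (TSS within 1,500 bp / gene body /
intergenic), island context (island / shore < 2 kb / shelf 2-4 kb / open
sea), cohort methylation class (hypo < 0.3 / hyper > 0.7 mean beta) and
chromatin-mark overlap across the pseudo cell lines; modality counts kernel-
density modes at least 1.2x the average bin density.
"""

from cistriad import SimConfig, annotate_cpgs, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=7, n_cpgs=500))
table = annotate_cpgs(cohort.cpgs, cohort.methylation.beta, cohort.genes,
                      cohort.islands, cohort.marks)

print(table["position_class"].value_counts().to_string())
print()
print(table["island_class"].value_counts().to_string())
print()
print(table["methylation_class"].value_counts().to_string())
print()
print("modes of the per-probe beta distribution:")
print(table["n_modes"].value_counts().sort_index().to_string())
print()
has_dhs = (table["n_lines_DHS"] >= 1)
hypo = table["methylation_class"] == "hypo"
print(f"DHS overlap among hypomethylated probes: {has_dhs[hypo].mean():.0%} "
      f"vs {has_dhs[~hypo].mean():.0%} elsewhere")
# Most probes are unimodal across individuals; multi-modal probes are the
# natural candidates for genotype-driven methylation.
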