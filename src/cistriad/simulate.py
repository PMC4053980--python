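"""Synthetic multi-omic cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a cohort of 62 individuals (expression assayed on a 58-sample
subset), biallelic SNP dosages in Hardy-Weinberg proportions with blockwise
local LD, bimodal CpG beta values with cis-acting genotype effects on the
logit scale, gene expression with cis-eQTL effects and signed coupling to
CpG methylation (one third of couplings positive), and per-SNP allelic
log2 ratios defined at heterozygous entries with contiguous same-sign
allelic-expression regions. Every planted effect is returned as ground
truth so recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .types import (
    AlleleRatioTrack,
    CpGProbe,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    GenotypeMatrix,
    MarkTrackSet,
    MethylationMatrix,
    SampleSet,
    SnpLocus,
    ValidationError,
)

MARK_NAMES = ("DHS", "H3K4me3", "H3K27me3", "H3K36me3")
# |logit| beyond this saturates the beta scale before noise is added
MAX_ABS_LOGIT_MEAN = 6.9


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 62
    n_expression_samples: int = 58
    n_genes: int = 200
    n_cpgs: int = 2_000
    n_snps: int = 5_000
    chrom: str = "chr1"
    chrom_length_bp: int = 20_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_bp: int = 20_000
    ld_flip_prob: float = 0.002
    hypo_fraction: float = 0.5
    tss_cpg_fraction: float = 0.4
    n_cell_lines: int = 5
    # planted effect counts and strengths
    n_mqtl: int = 100
    mqtl_rho_range: tuple[float, float] = (0.4, 0.8)
    n_joint: int = 10  # SNPs driving both a CpG and a gene (emQTL chains)
    joint_rho_range: tuple[float, float] = (0.7, 0.9)
    n_eqtl: int = 40
    eqtl_rho_range: tuple[float, float] = (0.5, 0.8)
    n_methexpr: int = 60
    methexpr_rho_range: tuple[float, float] = (0.5, 0.8)
    positive_coupling_fraction: float = 1.0 / 3.0
    n_ae_regions: int = 50
    ae_region_size: int = 5
    ae_signal: float = 0.6
    ae_carrier_prob: float = 0.3
    # noise scales
    meth_noise_sd: float = 0.3  # logit scale
    meth_baseline_spread: float = 0.4  # logit scale, within-mode
    expr_noise_sd: float = 1.0
    ae_noise_sd: float = 0.15
    seed: int | None = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes + 1, self.n_cpgs, self.n_snps) < 1:
            raise ConfigError("all counts must be >= 1")
        if self.n_expression_samples > self.n_samples:
            raise ConfigError("n_expression_samples must be <= n_samples")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        for frac in (self.hypo_fraction, self.tss_cpg_fraction,
                     self.positive_coupling_fraction):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.ae_region_size < 2:
            raise ConfigError("an aeRegion needs >= 2 SNPs")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth link between a locus and a target feature."""

    kind: str  # mqtl | eqtl | methexpr
    target_id: str
    locus_id: str
    effect_size: float  # slope in target units (logit scale for mqtl)
    sign: int
    target_rho: float  # correlation the effect was sized to reach


@dataclass(frozen=True)
class PlantedAeRegion:
    snp_indices: tuple[int, ...]  # consecutive in the track ordering
    sign: int
    signal: float
    carriers: tuple[int, ...]  # sample indices

    def __post_init__(self) -> None:
        if len(self.snp_indices) < 2:
            raise ConfigError("a planted AE region needs >= 2 SNPs")


@dataclass
class Cohort:
    config: SimConfig
    samples: SampleSet
    genes: list[GeneModel]
    cpgs: list[CpGProbe]
    snps: list[SnpLocus]
    islands: list[GenomicInterval]
    marks: MarkTrackSet
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    expression: ExpressionMatrix
    ae_track: AlleleRatioTrack
    effects: list[PlantedEffect] = field(default_factory=list)
    ae_regions_truth: list[PlantedAeRegion] = field(default_factory=list)


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[CpGProbe], list[SnpLocus],
           list[GenomicInterval], MarkTrackSet]:
    """Genes, CpG probes, SNPs, CpG islands and chromatin-mark tracks.

    Genes are non-overlapping on one synthetic chromosome; CpGs are placed
    with excess density within ±1,500 bp of TSSs (the configured fraction)
    and the rest uniformly; SNPs are uniform; marks are TSS-anchored
    intervals for the pseudo cell lines plus random background.
    """
    L = config.chrom_length_bp
    chrom = config.chrom
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        lengths = rng.integers(5_000, 50_000, size=config.n_genes)
        total = int(lengths.sum())
        if total >= L:
            raise ConfigError(
                f"chromosome of {L} bp too short for {config.n_genes} genes"
            )
        gaps = rng.dirichlet(np.ones(config.n_genes + 1)) * (L - total)
        cursor = 0.0
        for i in range(config.n_genes):
            cursor += gaps[i]
            start = int(cursor)
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(f"gene_{i + 1:04d}", chrom, tss, tes, strand))
            cursor = end

    islands: list[GenomicInterval] = []
    for gene in genes:
        if rng.random() < 0.6:
            half = int(rng.integers(200, 800))
            start = max(0, gene.tss - half)
            islands.append(
                GenomicInterval(chrom, start, min(L, gene.tss + half), None)
            )
    for _ in range(max(1, config.n_genes // 4)):
        start = int(rng.integers(0, max(1, L - 1_000)))
        islands.append(GenomicInterval(chrom, start, start + int(rng.integers(300, 1_000))))

    positions = []
    probe_types = []
    n_tss_cpgs = round(config.tss_cpg_fraction * config.n_cpgs) if genes else 0
    for _ in range(n_tss_cpgs):
        gene = genes[rng.integers(len(genes))]
        pos = int(np.clip(gene.tss + rng.integers(-1_500, 1_501), 0, L - 1))
        positions.append(pos)
        probe_types.append("I" if rng.random() < 0.6 else "II")
    for _ in range(config.n_cpgs - n_tss_cpgs):
        positions.append(int(rng.integers(0, L)))
        probe_types.append("I" if rng.random() < 0.1 else "II")
    order = np.argsort(positions, kind="mergesort")
    cpgs = [
        CpGProbe(f"cg_{k + 1:05d}", chrom, positions[i], probe_types[i])
        for k, i in enumerate(order)
    ]

    snp_positions = np.sort(
        rng.choice(L, size=config.n_snps, replace=False)
        if config.n_snps <= L
        else rng.integers(0, L, size=config.n_snps)
    )
    lo, hi = config.maf_range
    snps = [
        SnpLocus(f"rs_{k + 1:05d}", chrom, int(p), float(rng.uniform(lo, hi)))
        for k, p in enumerate(snp_positions)
    ]

    marks: MarkTrackSet = {}
    for mark in MARK_NAMES:
        marked_genes = [g for g in genes if rng.random() < 0.3]
        lines: dict[str, list[GenomicInterval]] = {}
        for line_idx in range(config.n_cell_lines):
            intervals: list[GenomicInterval] = []
            for gene in marked_genes:
                if rng.random() < 0.8:
                    jitter = int(rng.integers(0, 400))
                    start = max(0, gene.tss - 500 - jitter)
                    intervals.append(
                        GenomicInterval(chrom, start, min(L, gene.tss + 500 + jitter))
                    )
            for _ in range(10):
                start = int(rng.integers(0, max(1, L - 2_000)))
                intervals.append(
                    GenomicInterval(chrom, start, start + int(rng.integers(500, 2_000)))
                )
            intervals.sort(key=lambda iv: iv.start)
            lines[f"line_{line_idx + 1}"] = intervals
        marks[mark] = lines
    return genes, cpgs, snps, islands, marks


def simulate_genotypes(
    snps: list[SnpLocus], config: SimConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages with block-copy local LD.

    The first SNP of each LD block (blocks are ``ld_block_bp`` windows) is
    drawn Binomial(2, MAF) per sample; later SNPs in the block copy the
    previous SNP's dosages, re-drawing each sample with probability
    ``ld_flip_prob`` — so adjacent within-block R^2 ~ (1 - flip)^2 and
    across-block R^2 ~ 0. Each locus's MAF is reset to its realized value.
    """
    n = config.n_samples
    dosage = np.empty((len(snps), n))
    prev_block = None
    block_maf = 0.25
    for k, snp in enumerate(snps):
        block = (snp.chrom, snp.position // config.ld_block_bp)
        if block != prev_block:
            block_maf = snp.maf
            dosage[k] = rng.binomial(2, block_maf, size=n)
            prev_block = block
        else:
            row = dosage[k - 1].copy()
            redraw = rng.random(n) < config.ld_flip_prob
            row[redraw] = rng.binomial(2, block_maf, size=int(redraw.sum()))
            dosage[k] = row
    samples = SampleSet([f"s{j + 1:02d}" for j in range(n)])
    gm = GenotypeMatrix(list(snps), samples, dosage)
    freq = gm.realized_maf()
    gm.loci = [
        SnpLocus(s.snp_id, s.chrom, s.position, float(freq[k]))
        for k, s in enumerate(snps)
    ]
    return gm


def _slope_for_target_rho(rho: float, noise_sd: float, predictor_sd: float) -> float:
    """Linear slope giving correlation ``rho`` against noise of ``noise_sd``."""
    if predictor_sd == 0:
        raise ConfigError("cannot plant an effect on a constant predictor")
    if noise_sd == 0:
        return 1.0 if rho > 0 else -1.0
    return rho / math.sqrt(1.0 - rho * rho) * noise_sd / predictor_sd


def plant_joint_effects(
    genes: list[GeneModel],
    cpgs: list[CpGProbe],
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
    maf_min: float = 0.10,
) -> list[PlantedEffect]:
    """Plant SNPs that drive both a nearby CpG and a nearby gene.

    Each chain contributes an mQTL effect and an eQTL effect sharing the
    same locus, the ground truth for emQTL recovery. Gene and CpG targets
    are left for the marginal planting passes to skip.
    """
    snp_pos = genotypes.positions
    cpg_pos = np.array([p.position for p in cpgs])
    dosage_sd = genotypes.dosage.std(axis=1, ddof=1)
    maf = genotypes.realized_maf()
    effects: list[PlantedEffect] = []
    used_cpgs: set[int] = set()
    lo, hi = config.joint_rho_range
    for gi in rng.permutation(len(genes)):
        if len(effects) >= 2 * config.n_joint:
            break
        gene = genes[gi]
        a = np.searchsorted(snp_pos, gene.start - 100_000)
        b = np.searchsorted(snp_pos, gene.end + 100_000, side="right")
        snp_cands = [k for k in range(a, b) if dosage_sd[k] > 0 and maf[k] > maf_min]
        if not snp_cands:
            continue
        si = snp_cands[rng.integers(len(snp_cands))]
        ca = np.searchsorted(cpg_pos, snp_pos[si] - 100_000)
        cb = np.searchsorted(cpg_pos, snp_pos[si] + 100_000, side="right")
        cpg_cands = [c for c in range(ca, cb) if c not in used_cpgs]
        if not cpg_cands:
            continue
        ci = cpg_cands[rng.integers(len(cpg_cands))]
        used_cpgs.add(ci)
        rho = float(rng.uniform(lo, hi))
        sign = 1 if rng.random() < 0.5 else -1
        effects.append(
            PlantedEffect(
                "mqtl", cpgs[ci].probe_id, genotypes.loci[si].snp_id,
                sign * _slope_for_target_rho(rho, config.meth_noise_sd, dosage_sd[si]),
                sign, rho,
            )
        )
        sign_e = 1 if rng.random() < 0.5 else -1
        effects.append(
            PlantedEffect(
                "eqtl", gene.gene_id, genotypes.loci[si].snp_id,
                sign_e * _slope_for_target_rho(rho, config.expr_noise_sd, dosage_sd[si]),
                sign_e, rho,
            )
        )
    return effects


def plant_mqtl_effects(
    cpgs: list[CpGProbe],
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
    max_distance: int = 100_000,
    maf_min: float = 0.10,
    exclude_cpgs: set[str] | None = None,
) -> list[PlantedEffect]:
    """Choose cis CpG-SNP pairs and size logit-scale slopes to target rho.

    Only SNPs whose realized minor allele frequency clears the mapping
    filter are eligible, so every planted effect is discoverable.
    """
    snp_pos = genotypes.positions
    dosage_sd = genotypes.dosage.std(axis=1, ddof=1)
    maf = genotypes.realized_maf()
    usable_cpgs = rng.permutation(len(cpgs))
    effects: list[PlantedEffect] = []
    lo, hi = config.mqtl_rho_range
    exclude = exclude_cpgs or set()
    for ci in usable_cpgs:
        if len(effects) >= config.n_mqtl:
            break
        probe = cpgs[ci]
        if probe.probe_id in exclude:
            continue
        a = np.searchsorted(snp_pos, probe.position - max_distance)
        b = np.searchsorted(snp_pos, probe.position + max_distance, side="right")
        candidates = [
            k for k in range(a, b) if dosage_sd[k] > 0 and maf[k] > maf_min
        ]
        if not candidates:
            continue
        si = candidates[rng.integers(len(candidates))]
        rho = float(rng.uniform(lo, hi))
        sign = 1 if rng.random() < 0.5 else -1
        slope = sign * _slope_for_target_rho(rho, config.meth_noise_sd, dosage_sd[si])
        effects.append(
            PlantedEffect(
                "mqtl", probe.probe_id, genotypes.loci[si].snp_id, slope, sign, rho
            )
        )
    return effects


def simulate_methylation(
    genotypes: GenotypeMatrix,
    cpgs: list[CpGProbe],
    effects: list[PlantedEffect],
    config: SimConfig,
    rng: np.random.Generator,
) -> MethylationMatrix:
    """Bimodal beta values with additive cis genotype effects on the logit scale.

    Each CpG's baseline is drawn from a two-component mixture (hypomethylated
    mode centered at beta 0.15, hypermethylated at 0.85, within-mode spread
    on the logit scale); planted mQTL effects add slope x dosage on the logit
    scale, noise is i.i.d. Gaussian on the logit scale and the inverse logit
    keeps every value inside (0, 1).
    """
    probe_index = {p.probe_id: k for k, p in enumerate(cpgs)}
    snp_index = {s.snp_id: k for k, s in enumerate(genotypes.loci)}
    n = config.n_samples
    hypo = rng.random(len(cpgs)) < config.hypo_fraction
    centers = np.where(hypo, logit(0.15), logit(0.85))
    baseline = centers + rng.normal(0, config.meth_baseline_spread, size=len(cpgs))
    logits = np.tile(baseline[:, None], (1, n))
    for eff in effects:
        if eff.kind != "mqtl":
            continue
        if eff.target_id not in probe_index or eff.locus_id not in snp_index:
            raise ConfigError(f"effect references unknown feature: {eff}")
        ci, si = probe_index[eff.target_id], snp_index[eff.locus_id]
        mean_extreme = max(
            abs(baseline[ci]), abs(baseline[ci] + 2 * eff.effect_size)
        )
        if mean_extreme > MAX_ABS_LOGIT_MEAN:
            raise ConfigError(
                f"mQTL effect on {eff.target_id} saturates the beta scale"
            )
        logits[ci] += eff.effect_size * genotypes.dosage[si]
    if config.meth_noise_sd > 0:
        logits = logits + rng.normal(0, config.meth_noise_sd, size=logits.shape)
    return MethylationMatrix(list(cpgs), genotypes.samples, expit(logits))


def plant_expression_effects(
    genes: list[GeneModel],
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    config: SimConfig,
    rng: np.random.Generator,
    maf_min: float = 0.10,
    exclude_genes: set[str] | None = None,
) -> list[PlantedEffect]:
    """Choose disjoint eQTL genes and methylation-coupled genes with sized slopes."""
    snp_pos = genotypes.positions
    cpg_pos = methylation.positions
    dosage_sd = genotypes.dosage.std(axis=1, ddof=1)
    maf = genotypes.realized_maf()
    beta_sd = methylation.beta.std(axis=1, ddof=1)
    gene_order = rng.permutation(len(genes))
    effects: list[PlantedEffect] = []
    exclude = exclude_genes or set()
    n_eqtl = 0
    n_coupled = 0
    for gi in gene_order:
        gene = genes[gi]
        if gene.gene_id in exclude:
            continue
        if n_eqtl < config.n_eqtl:
            a = np.searchsorted(snp_pos, gene.start - 100_000)
            b = np.searchsorted(snp_pos, gene.end + 100_000, side="right")
            candidates = [
                k for k in range(a, b) if dosage_sd[k] > 0 and maf[k] > maf_min
            ]
            if candidates:
                si = candidates[rng.integers(len(candidates))]
                rho = float(rng.uniform(*config.eqtl_rho_range))
                sign = 1 if rng.random() < 0.5 else -1
                slope = sign * _slope_for_target_rho(
                    rho, config.expr_noise_sd, dosage_sd[si]
                )
                effects.append(
                    PlantedEffect(
                        "eqtl", gene.gene_id, genotypes.loci[si].snp_id,
                        slope, sign, rho,
                    )
                )
                n_eqtl += 1
                continue
        if n_coupled < config.n_methexpr:
            a = np.searchsorted(cpg_pos, gene.start - 100_000)
            b = np.searchsorted(cpg_pos, gene.end + 100_000, side="right")
            candidates = [k for k in range(a, b) if beta_sd[k] > 0]
            if candidates:
                ci = candidates[rng.integers(len(candidates))]
                rho = float(rng.uniform(*config.methexpr_rho_range))
                sign = 1 if rng.random() < config.positive_coupling_fraction else -1
                slope = sign * _slope_for_target_rho(
                    rho, config.expr_noise_sd, beta_sd[ci]
                )
                effects.append(
                    PlantedEffect(
                        "methexpr", gene.gene_id,
                        methylation.probes[ci].probe_id, slope, sign, rho,
                    )
                )
                n_coupled += 1
        if n_eqtl >= config.n_eqtl and n_coupled >= config.n_methexpr:
            break
    return effects


def simulate_expression(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    genes: list[GeneModel],
    effects: list[PlantedEffect],
    config: SimConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Gene expression with cis-eQTL effects and signed methylation coupling.

    expression = baseline + sum(slope x dosage) + sum(coupling x beta) +
    Gaussian noise; columns outside the expression sample subset are missing.
    """
    gene_index = {g.gene_id: k for k, g in enumerate(genes)}
    snp_index = {s.snp_id: k for k, s in enumerate(genotypes.loci)}
    probe_index = {p.probe_id: k for k, p in enumerate(methylation.probes)}
    n = config.n_samples
    level = np.tile(rng.normal(8.0, 1.5, size=len(genes))[:, None], (1, n))
    for eff in effects:
        if eff.kind == "eqtl":
            if eff.target_id not in gene_index or eff.locus_id not in snp_index:
                raise ConfigError(f"effect references unknown feature: {eff}")
            level[gene_index[eff.target_id]] += (
                eff.effect_size * genotypes.dosage[snp_index[eff.locus_id]]
            )
        elif eff.kind == "methexpr":
            if eff.target_id not in gene_index or eff.locus_id not in probe_index:
                raise ConfigError(f"coupled CpG not simulated: {eff}")
            level[gene_index[eff.target_id]] += (
                eff.effect_size * methylation.beta[probe_index[eff.locus_id]]
            )
    if config.expr_noise_sd > 0:
        level = level + rng.normal(0, config.expr_noise_sd, size=level.shape)
    mask = np.zeros(n, dtype=bool)
    mask[: config.n_expression_samples] = True
    level[:, ~mask] = np.nan
    samples = SampleSet(
        list(genotypes.samples.sample_ids), {"expression": mask}
    )
    return ExpressionMatrix(list(genes), samples, level)


def plant_ae_regions(
    genotypes: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> list[PlantedAeRegion]:
    """Non-overlapping runs of consecutive SNPs with carrier samples."""
    size = config.ae_region_size
    gap = 2  # null SNPs kept between regions so truth runs stay distinct
    n_snps = len(genotypes.loci)
    max_regions = max(0, (n_snps - size) // (size + gap) + 1)
    if config.n_ae_regions > max_regions:
        raise ConfigError(
            f"cannot place {config.n_ae_regions} regions of {size} SNPs "
            f"among {n_snps} SNPs"
        )
    starts = []
    slots = rng.permutation(max_regions)[: config.n_ae_regions]
    for slot in np.sort(slots):
        starts.append(int(slot) * (size + gap))
    regions = []
    n = config.n_samples
    for start in starts:
        sign = 1 if rng.random() < 0.5 else -1
        carriers = np.flatnonzero(rng.random(n) < config.ae_carrier_prob)
        while carriers.size < 2:
            carriers = np.flatnonzero(rng.random(n) < config.ae_carrier_prob)
        regions.append(
            PlantedAeRegion(
                snp_indices=tuple(range(start, start + size)),
                sign=sign,
                signal=config.ae_signal,
                carriers=tuple(int(c) for c in carriers),
            )
        )
    return regions


def simulate_allelic_expression(
    genotypes: GenotypeMatrix,
    snps: list[SnpLocus],
    planted_regions: list[PlantedAeRegion],
    config: SimConfig,
    rng: np.random.Generator,
) -> AlleleRatioTrack:
    """Allelic log2 ratios on heterozygous entries with planted AE regions.

    Entries are defined only where dosage = 1. Inside a planted region a
    carrier sample adds the region's persistent signed signal; all observed
    entries carry i.i.d. Gaussian noise around that mean (pure noise around
    zero elsewhere).
    """
    het = genotypes.dosage == 1
    n_loci, n = het.shape
    raw = np.where(het, rng.normal(0, config.ae_noise_sd, size=het.shape), np.nan)
    for region in planted_regions:
        for k in region.snp_indices:
            if k >= n_loci:
                raise ConfigError("planted region indexes beyond the SNP track")
            for j in region.carriers:
                if het[k, j]:
                    raw[k, j] += region.sign * region.signal
    return AlleleRatioTrack(list(snps), genotypes.samples, raw)


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full cohort: annotation, genotypes, methylation, expression,
    allelic track, and the planted ground truth."""
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    genes, cpgs, snps, islands, marks = simulate_annotation(config, rng)
    genotypes = simulate_genotypes(snps, config, rng)
    joint = (
        plant_joint_effects(genes, cpgs, genotypes, config, rng)
        if config.n_joint > 0
        else []
    )
    joint_cpgs = {e.target_id for e in joint if e.kind == "mqtl"}
    joint_genes = {e.target_id for e in joint if e.kind == "eqtl"}
    effects = joint + plant_mqtl_effects(
        cpgs, genotypes, config, rng, exclude_cpgs=joint_cpgs
    )
    methylation = simulate_methylation(genotypes, cpgs, effects, config, rng)
    expr_effects = plant_expression_effects(
        genes, genotypes, methylation, config, rng, exclude_genes=joint_genes
    )
    effects = effects + expr_effects
    expression = simulate_expression(
        genotypes, methylation, genes, effects, config, rng
    )
    ae_truth = plant_ae_regions(genotypes, config, rng)
    ae_track = simulate_allelic_expression(genotypes, snps, ae_truth, config, rng)
    return Cohort(
        config=config,
        samples=genotypes.samples,
        genes=genes,
        cpgs=cpgs,
        snps=snps,
        islands=islands,
        marks=marks,
        genotypes=genotypes,
        methylation=methylation,
        expression=expression,
        ae_track=ae_track,
        effects=effects,
        ae_regions_truth=ae_truth,
    )


def truth_table(cohort: Cohort):
    """Planted effects as a flat table (for the simulate CLI's truth.tsv)."""
    import pandas as pd

    rows = [
        {
            "kind": e.kind,
            "target_id": e.target_id,
            "locus_id": e.locus_id,
            "effect_size": e.effect_size,
            "sign": e.sign,
            "target_rho": e.target_rho,
        }
        for e in cohort.effects
    ]
    for r in cohort.ae_regions_truth:
        rows.append(
            {
                "kind": "ae_region",
                "target_id": ";".join(
                    cohort.snps[k].snp_id for k in r.snp_indices
                ),
                "locus_id": "",
                "effect_size": r.signal,
                "sign": r.sign,
                "target_rho": float("nan"),
            }
        )
    return pd.DataFrame(rows)
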