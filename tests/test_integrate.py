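import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from cistriad import (
    AeRegion,
    GeneModel,
    SimConfig,
    ValidationError,
    build_cis_pairs,
    find_emqtls,
    independent_fraction,
    maf_matched_enrichment,
    overlap_sets,
    permutation_fdr_map,
    proliferation_variance,
    proliferation_vector,
    simulate_annotation,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
    term_enrichment,
    variance_partition,
)
from cistriad.mapping import AssociationResult, NullDistribution
from cistriad.simulate import PlantedEffect


def fake_result(sig_pairs, mode, fdr=0.05):
    """Minimal AssociationResult carrying given significant (feature, locus)."""
    rows = [
        {
            "feature_id": f, "locus_id": l, "rho": 0.9, "p_empirical": 1e-4,
            "distance_bp": 0, "significant": True, "feature_idx": 0,
            "locus_idx": 0, "n_informative": 62,
        }
        for f, l in sig_pairs
    ]
    pairs = pd.DataFrame(
        rows,
        columns=["feature_id", "locus_id", "rho", "p_empirical", "distance_bp",
                 "significant", "feature_idx", "locus_idx", "n_informative"],
    )
    null = NullDistribution(np.array([0.1]), 1, len(rows), seed=0)
    return AssociationResult(pairs, 0.5, 1e-3, fdr, mode, null)


class TestFindEmqtls:
    def test_disjoint_significant_sets_give_empty_emqtls(self):
        mqtl = fake_result([("cg1", "rs1")], "mqtl")
        eqtl = fake_result([("g1", "rs2")], "eqtl")
        out = find_emqtls(mqtl, eqtl)
        assert out.snp_ids == set()

    def test_snp_shared_by_mqtl_and_eqtl_is_member(self):
        mqtl = fake_result([("cg1", "rs1")], "mqtl")
        eqtl = fake_result([("g1", "rs1")], "eqtl")
        out = find_emqtls(mqtl, eqtl)
        assert out.snp_ids == {"rs1"}
        assert out.via_eqtl == {"rs1"}
        assert out.gene_ids == {"g1"}

    def test_aeqtl_arm_maps_regions_to_overlapped_genes(self):
        mqtl = fake_result([("cg1", "rs1"), ("cg2", "rs2")], "mqtl")
        eqtl = fake_result([], "eqtl")
        aeqtl = fake_result([("aer_1", "rs1"), ("aer_2", "rs2")], "aeqtl")
        regions = [
            AeRegion("aer_1", "chr1", 1000, 2000, ["a", "b"], 1, np.zeros(2)),
            AeRegion("aer_2", "chr1", 9000, 9500, ["c", "d"], -1, np.zeros(2)),
        ]
        genes = [GeneModel("g1", "chr1", 500, 1500, "+")]
        out = find_emqtls(mqtl, eqtl, aeqtl, aeregions=regions, genes=genes)
        assert out.snp_ids == {"rs1", "rs2"}
        assert out.gene_ids == {"g1"}  # aer_1 overlaps g1
        assert out.aeregions_without_gene == {"aer_2"}

    def test_fdr_levels_must_match(self):
        mqtl = fake_result([("cg1", "rs1")], "mqtl", fdr=0.05)
        eqtl = fake_result([("g1", "rs1")], "eqtl", fdr=0.10)
        with pytest.raises(ValidationError):
            find_emqtls(mqtl, eqtl)

    def test_overlap_sets_venn_counts(self):
        mqtl = fake_result([("cg1", "rs1"), ("cg2", "rs2")], "mqtl")
        eqtl = fake_result([("g1", "rs1")], "eqtl")
        aeqtl = fake_result([("aer_1", "rs2"), ("aer_2", "rs3")], "aeqtl")
        venn = overlap_sets(mqtl, eqtl, aeqtl)
        assert venn["mqtl"] == 2 and venn["eqtl"] == 1 and venn["aeqtl"] == 2
        assert venn["mqtl&eqtl"] == 1 and venn["mqtl&aeqtl"] == 1
        assert venn["emqtl"] == 2

    def test_planted_joint_effect_recovered_end_to_end(self):
        # one SNP drives both a CpG and a gene; it must surface as an emQTL
        config = SimConfig(
            seed=91, n_genes=25, n_cpgs=120, n_snps=250, n_mqtl=0, n_eqtl=0,
            n_methexpr=0, n_joint=0, n_ae_regions=2, chrom_length_bp=2_500_000,
        )
        rng = np.random.default_rng(config.seed)
        genes, cpgs, snps, islands, marks = simulate_annotation(config, rng)
        genotypes = simulate_genotypes(snps, config, rng)
        maf = genotypes.realized_maf()
        gene = genes[10]
        snp_pos = genotypes.positions
        near = [
            k for k in range(len(snps))
            if abs(snp_pos[k] - gene.tss) < 100_000 and maf[k] > 0.15
        ]
        si = near[0]
        cpg_near = min(
            range(len(cpgs)), key=lambda c: abs(cpgs[c].position - snp_pos[si])
        )
        dosage_sd = genotypes.dosage[si].std(ddof=1)
        slope_m = 0.85 / math.sqrt(1 - 0.85**2) * config.meth_noise_sd / dosage_sd
        slope_e = 0.85 / math.sqrt(1 - 0.85**2) * config.expr_noise_sd / dosage_sd
        effects = [
            PlantedEffect("mqtl", cpgs[cpg_near].probe_id,
                          genotypes.loci[si].snp_id, slope_m, 1, 0.85),
            PlantedEffect("eqtl", gene.gene_id,
                          genotypes.loci[si].snp_id, slope_e, 1, 0.85),
        ]
        methylation = simulate_methylation(genotypes, cpgs, effects, config, rng)
        expression = simulate_expression(
            genotypes, methylation, genes, effects, config, rng
        )
        mqtl_pairs = build_cis_pairs(cpgs, genotypes.loci, "mqtl")
        mqtl = permutation_fdr_map(
            methylation.beta, genotypes.dosage, mqtl_pairs, seed=92
        )
        eqtl_pairs = build_cis_pairs(genes, genotypes.loci, "eqtl")
        eqtl = permutation_fdr_map(
            expression.level, genotypes.dosage, eqtl_pairs, seed=93
        )
        out = find_emqtls(mqtl, eqtl)
        assert genotypes.loci[si].snp_id in out.snp_ids
        assert gene.gene_id in out.gene_ids


class TestMafMatchedEnrichment:
    @staticmethod
    def _maf(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(
            rng.uniform(0.1, 0.5, size=n), index=[f"rs{i}" for i in range(n)]
        )

    def test_reference_equal_to_pool_gives_fold_one(self):
        maf = self._maf(400)
        target = set(maf.index[:60])
        fold = maf_matched_enrichment(target, set(maf.index), maf,
                                      n_draws=200, seed=1)
        assert fold == pytest.approx(1.0)

    def test_random_target_gives_fold_about_one(self):
        maf = self._maf(2000)
        rng = np.random.default_rng(2)
        target = set(rng.choice(maf.index, size=150, replace=False))
        reference = set(rng.choice(maf.index, size=500, replace=False))
        fold = maf_matched_enrichment(target, reference, maf, n_draws=400, seed=3)
        assert fold == pytest.approx(1.0, abs=0.2)

    def test_constructed_threefold_enrichment_recovered(self):
        maf = self._maf(2000, seed=4)
        rng = np.random.default_rng(5)
        reference = set(rng.choice(maf.index, size=500, replace=False))
        # expected matched overlap is |target| * 500/2000; put 75% of the
        # target inside the reference for a 3x excess
        inside = rng.choice(sorted(reference), size=90, replace=False)
        outside = rng.choice(
            sorted(set(maf.index) - reference), size=30, replace=False
        )
        target = set(inside) | set(outside)
        fold = maf_matched_enrichment(target, reference, maf, n_draws=400, seed=6)
        assert fold == pytest.approx(3.0, abs=0.45)

    def test_invariant_to_snp_relabeling(self):
        maf = self._maf(300, seed=7)
        rng = np.random.default_rng(8)
        target = set(rng.choice(maf.index, size=40, replace=False))
        reference = set(rng.choice(maf.index, size=80, replace=False))
        fold = maf_matched_enrichment(target, reference, maf, n_draws=200, seed=9)
        relabel = {s: f"snp_{i}" for i, s in enumerate(maf.index)}
        maf2 = pd.Series(maf.to_numpy(), index=[relabel[s] for s in maf.index])
        fold2 = maf_matched_enrichment(
            {relabel[s] for s in target}, {relabel[s] for s in reference},
            maf2, n_draws=200, seed=9,
        )
        assert fold == pytest.approx(fold2)

    def test_requires_maf_for_all_snps(self):
        maf = self._maf(10)
        with pytest.raises(ValidationError):
            maf_matched_enrichment({"ghost"}, set(maf.index), maf, n_draws=100)


class TestVariancePartition:
    def test_pure_noise_explains_nothing(self, rng):
        y = rng.normal(size=60)
        Xg = rng.binomial(2, 0.3, size=(20, 60)).astype(float)
        Xm = rng.uniform(size=(20, 60))
        part = variance_partition(y, Xg, Xm, seed=0)
        assert part.r2_seq < 0.15
        assert part.r2_meth < 0.15

    def test_planted_fraction_recovered(self):
        # expression = b * dosage + small noise, b sized for an 80% variance
        # fraction; pooled out-of-fold R^2 must recover it within 0.1
        results = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            g = rng.binomial(2, 0.4, size=62).astype(float)
            noise = rng.normal(0, 1, size=62)
            b = 2.0 / g.std(ddof=1)  # planted variance fraction 0.8
            y = b * g + noise
            Xg = np.vstack([g, rng.binomial(2, 0.3, size=(8, 62))]).astype(float)
            Xm = rng.uniform(size=(5, 62))
            part = variance_partition(y, Xg, Xm, seed=seed)
            results.append(part.r2_seq)
        assert np.mean(results) == pytest.approx(0.8, abs=0.1)

    def test_reported_independent_fraction_formula(self):
        # on the percent scale: 5.9 / 8.9 rounds to 66%
        assert round(100 * independent_fraction(8.9, 5.9)) == 66

    def test_independent_meth_effect_survives_sequence_removal(self):
        fractions = []
        for seed in range(6):
            rng = np.random.default_rng(200 + seed)
            g = rng.binomial(2, 0.4, size=62).astype(float)
            m = rng.uniform(0.2, 0.8, size=62)  # independent of g
            y = 0.8 * g + 3.0 * m + rng.normal(0, 0.6, size=62)
            Xg = np.vstack([g, rng.binomial(2, 0.3, size=(5, 62))]).astype(float)
            Xm = np.vstack([m, rng.uniform(size=(5, 62))])
            part = variance_partition(y, Xg, Xm, seed=seed)
            fractions.append(part.independent_fraction)
        assert np.nanmean(fractions) > 0.7

    def test_methylation_determined_by_genotype_contributes_nothing_extra(self):
        fractions = []
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            g = rng.binomial(2, 0.4, size=62).astype(float)
            m = 0.1 + 0.35 * g  # deterministic function of the genotype
            y = 1.2 * g + rng.normal(0, 0.8, size=62)
            Xg = np.vstack([g, rng.binomial(2, 0.3, size=(5, 62))]).astype(float)
            Xm = np.vstack([m, rng.uniform(size=(5, 62))])
            part = variance_partition(y, Xg, Xm, seed=seed)
            if part.r2_meth > 0:
                fractions.append(part.independent_fraction)
        assert np.mean(fractions) < 0.15

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            variance_partition(
                rng.normal(size=10), rng.normal(size=(3, 10)),
                rng.normal(size=(3, 10)),
            )


class TestProliferation:
    def test_targets_independent_of_vector_explain_nothing(self, rng):
        markers = rng.normal(size=(42, 62))
        vector = proliferation_vector(markers)
        targets = rng.normal(size=(30, 62))
        assert proliferation_variance(targets, vector) < 0.1

    def test_constructed_variance_ratio_recovered(self, rng):
        markers = np.outer(rng.normal(size=42), rng.normal(size=62))
        markers += rng.normal(0, 0.05, size=markers.shape)
        vector = proliferation_vector(markers)
        v = (vector - vector.mean()) / vector.std()
        # target = a*v + e with var(a*v)/var(target) = 0.4
        targets = []
        for _ in range(40):
            e = rng.normal(0, 1, size=62)
            e = (e - e.mean()) / e.std()
            targets.append(np.sqrt(0.4) * v + np.sqrt(0.6) * e)
        frac = proliferation_variance(np.array(targets), vector)
        assert frac == pytest.approx(0.4, abs=0.06)

    def test_zero_variance_target_skipped(self, rng):
        markers = rng.normal(size=(5, 30))
        vector = proliferation_vector(markers)
        targets = np.vstack([rng.normal(size=30), np.full(30, 0.7)])
        frac = proliferation_variance(targets, vector)
        assert np.isfinite(frac)

    def test_needs_two_marker_genes(self, rng):
        with pytest.raises(ValidationError):
            proliferation_vector(rng.normal(size=(1, 30)))


class TestTermEnrichment:
    def test_direct_fold_formula(self):
        background = {f"g{i}" for i in range(100)}
        test = {f"g{i}" for i in range(10)}
        annotations = {g: {"TERM"} for g in list(background)[:50]}
        # make sure the whole test set carries the term
        annotations.update({g: {"TERM"} for g in test})
        with_term = {g for g, t in annotations.items() if "TERM" in t}
        results = term_enrichment(test, background, annotations)
        expected_fold = 1.0 / (len(with_term) / 100)
        assert results[0].fold_enrichment == pytest.approx(expected_fold)

    def test_fisher_p_matches_hypergeometric_tail_sum(self):
        # 2x2 table a=8, b=2, c=10, d=80: two-sided Fisher p equals the sum
        # of hypergeometric probabilities no larger than the observed one
        background = {f"g{i}" for i in range(100)}
        test = {f"g{i}" for i in range(10)}
        with_term = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(10, 20)}
        annotations = {g: {"T"} for g in with_term}
        results = term_enrichment(test, background, annotations)
        n_term = 18
        rv = hypergeom(100, n_term, 10)
        p_obs = rv.pmf(8)
        expected = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert results[0].p_value == pytest.approx(expected, rel=1e-6)

    def test_null_draws_give_uniformish_pvalues(self, rng):
        background = {f"g{i}" for i in range(400)}
        annotations = {}
        for g in background:
            terms = {f"T{k}" for k in range(20) if rng.random() < 0.15}
            if terms:
                annotations[g] = terms
        test = set(rng.choice(sorted(background), size=60, replace=False))
        results = term_enrichment(test, background, annotations)
        frac_sig = np.mean([r.p_value < 0.05 for r in results])
        assert frac_sig < 0.20
        folds = [r.fold_enrichment for r in results]
        assert np.mean(folds) == pytest.approx(1.0, abs=0.25)

    def test_test_set_must_be_subset(self):
        with pytest.raises(ValidationError):
            term_enrichment({"x"}, {"y"}, {})
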