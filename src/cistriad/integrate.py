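"""Integration of the mapping results across modalities.

- emQTLs: SNPs significant both for methylation (mQTL) and for expression
  (eQTL and/or aeQTL) at the same FDR; reported with the genes they link to
  (directly via eQTLs, or via genes overlapped by their aeRegions).
- MAF-matched enrichment: how much more often a target SNP set falls in a
  reference set than random draws matched on minor-allele-frequency bins.
- Variance partitioning: cross-validated fraction of a gene's expression
  variance explained by cis genotypes, by cis methylation, and by
  methylation after the genotype model's fit is removed; the ratio of the
  last two is the methylation contribution independent of sequence.
- Cell-proliferation attribution and gene-set term enrichment.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import AssociationResult
from .types import AeRegion, GeneModel, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EmqtlSet:
    snp_ids: set[str]
    via_eqtl: set[str]
    via_aeqtl: set[str]
    gene_ids: set[str]
    aeregion_ids: set[str]
    aeregions_without_gene: set[str] = field(default_factory=set)


def _overlaps(region: AeRegion, gene: GeneModel) -> bool:
    return (
        region.chrom == gene.chrom
        and region.start < gene.end
        and gene.start < region.end
    )


def find_emqtls(
    mqtl: AssociationResult,
    eqtl: AssociationResult,
    aeqtl: AssociationResult | None = None,
    aeregions: list[AeRegion] | None = None,
    genes: list[GeneModel] | None = None,
) -> EmqtlSet:
    """SNPs significant for methylation AND for expression (eQTL or aeQTL).

    Gene membership combines genes linked by eQTL arms with genes overlapped
    by aeRegions linked through aeQTL arms; aeRegions overlapping no
    annotated gene are reported separately.
    """
    for other in (eqtl, aeqtl):
        if other is not None and not math.isclose(other.fdr, mqtl.fdr):
            raise ValidationError("all mapping results must share the FDR level")
    mqtl_snps = mqtl.significant_loci()
    eqtl_snps = eqtl.significant_loci()
    aeqtl_snps = aeqtl.significant_loci() if aeqtl is not None else set()
    emqtl_snps = mqtl_snps & (eqtl_snps | aeqtl_snps)

    esig = eqtl.significant
    gene_ids = set(esig[esig["locus_id"].isin(emqtl_snps)]["feature_id"])
    region_ids: set[str] = set()
    regions_without_gene: set[str] = set()
    if aeqtl is not None:
        asig = aeqtl.significant
        region_ids = set(asig[asig["locus_id"].isin(emqtl_snps)]["feature_id"])
        if aeregions is not None and genes is not None:
            by_id = {r.region_id: r for r in aeregions}
            for rid in region_ids:
                region = by_id.get(rid)
                if region is None:
                    continue
                hits = {g.gene_id for g in genes if _overlaps(region, g)}
                if hits:
                    gene_ids |= hits
                else:
                    regions_without_gene.add(rid)
    return EmqtlSet(
        snp_ids=emqtl_snps,
        via_eqtl=emqtl_snps & eqtl_snps,
        via_aeqtl=emqtl_snps & aeqtl_snps,
        gene_ids=gene_ids,
        aeregion_ids=region_ids,
        aeregions_without_gene=regions_without_gene,
    )


def overlap_sets(
    mqtl: AssociationResult,
    eqtl: AssociationResult,
    aeqtl: AssociationResult | None = None,
) -> dict[str, int]:
    """Venn counts of significant SNPs across the three maps."""
    m = mqtl.significant_loci()
    e = eqtl.significant_loci()
    a = aeqtl.significant_loci() if aeqtl is not None else set()
    return {
        "mqtl": len(m),
        "eqtl": len(e),
        "aeqtl": len(a),
        "mqtl&eqtl": len(m & e),
        "mqtl&aeqtl": len(m & a),
        "eqtl&aeqtl": len(e & a),
        "mqtl&eqtl&aeqtl": len(m & e & a),
        "emqtl": len(m & (e | a)),
    }


def maf_matched_enrichment(
    target_snps: set[str],
    reference_snps: set[str],
    maf: pd.Series,
    n_draws: int = 1000,
    seed: int | None = None,
    bin_width: float = 0.05,
) -> float:
    """Fold enrichment of target∩reference over MAF-matched random draws.

    SNPs are binned by MAF (default 5%-wide bins); each random draw samples
    as many SNPs per bin as the target set holds there, from the full pool,
    and the fold is observed overlap divided by the mean random overlap.
    """
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    missing = (target_snps | reference_snps) - set(maf.index)
    if missing:
        raise ValidationError(f"MAF missing for {len(missing)} SNPs")
    rng = np.random.default_rng(seed)
    bins = (maf / bin_width).astype(int)
    observed = len(target_snps & reference_snps)
    reference_arr = maf.index.isin(reference_snps)
    draws = np.zeros(n_draws)
    for b, bin_ids in maf.groupby(bins).groups.items():
        n_target_bin = sum(1 for s in target_snps if bins[s] == b)
        if n_target_bin == 0:
            continue
        pool = np.flatnonzero(bins.loc[maf.index].to_numpy() == b)
        replace = pool.size < n_target_bin
        if replace:
            warnings.warn(f"MAF bin {b}: sampling with replacement")
        for d in range(n_draws):
            pick = rng.choice(pool, size=n_target_bin, replace=replace)
            draws[d] += reference_arr[pick].sum()
    mean_random = draws.mean()
    if mean_random == 0:
        return math.inf if observed > 0 else math.nan
    return observed / mean_random


def _forward_aic_ols(
    y: np.ndarray, X: np.ndarray, max_features: int
) -> np.ndarray:
    """Greedy forward selection by RSS with an AIC stop; returns coefficients
    of the fitted model on the selected columns (full-length, zeros else).

    AIC here is the Gaussian form n*log(RSS/n) + 2k (k = predictors incl.
    intercept); a feature is added only while AIC decreases.
    """
    n = y.size
    selected: list[int] = []
    resid = y - y.mean()
    rss = float(resid @ resid)
    aic = n * math.log(max(rss / n, 1e-300)) + 2.0
    available = list(range(X.shape[1]))
    while available and len(selected) < max_features:
        best = None
        for j in available:
            cols = selected + [j]
            design = np.column_stack([np.ones(n), X[:, cols]])
            coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
            r = y - design @ coef
            rss_j = float(r @ r)
            if best is None or rss_j < best[1]:
                best = (j, rss_j)
        j, rss_j = best
        aic_j = n * math.log(max(rss_j / n, 1e-300)) + 2.0 * (len(selected) + 2)
        if aic_j >= aic:
            break
        selected.append(j)
        available.remove(j)
        aic = aic_j
    beta = np.zeros(X.shape[1] + 1)
    if selected:
        design = np.column_stack([np.ones(n), X[:, selected]])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        beta[0] = coef[0]
        beta[np.array(selected) + 1] = coef[1:]
    else:
        beta[0] = y.mean()
    return beta


def _cv_predict(
    y: np.ndarray, X: np.ndarray, k_features: int, folds: int, rng: np.random.Generator
) -> np.ndarray:
    n = y.size
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(order, folds)):
        fold_of[chunk] = k
    pred = np.empty(n)
    for k in range(folds):
        test = fold_of == k
        beta = _forward_aic_ols(y[~test], X[~test], k_features)
        pred[test] = beta[0] + X[test] @ beta[1:]
    return pred


def _pooled_r2(y: np.ndarray, pred: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    r = float(np.corrcoef(y, pred)[0, 1])
    return max(r, 0.0) ** 2 if r > 0 else 0.0


@dataclass
class VariancePartition:
    r2_seq: float
    r2_meth: float
    r2_meth_given_seq: float

    @property
    def independent_fraction(self) -> float:
        if self.r2_meth <= 0:
            return math.nan
        return min(self.r2_meth_given_seq / self.r2_meth, 1.0)


def variance_partition(
    expression: np.ndarray,
    cis_dosage: np.ndarray,
    cis_beta: np.ndarray,
    k_features: int = 5,
    folds: int = 5,
    seed: int | None = None,
) -> VariancePartition:
    """Cross-validated variance decomposition for one gene.

    Per fold, up to ``k_features`` cis SNPs are chosen by greedy forward
    selection with an AIC stop on the training samples and the fitted linear
    model predicts the held-out fold; r2_seq is the squared Pearson
    correlation between observations and pooled out-of-fold predictions
    (negative correlations clipped to zero). r2_meth repeats this with cis
    CpG betas, and r2_meth_given_seq applies the methylation procedure to
    the out-of-fold residuals of the sequence model.

    ``expression`` is a length-n vector; ``cis_dosage`` and ``cis_beta`` are
    candidate-by-sample matrices restricted to the gene's cis window.
    """
    y = np.asarray(expression, dtype=float)
    n = y.size
    if n < folds * 4:
        raise ValidationError(f"need >= {folds * 4} samples for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    Xg = np.asarray(cis_dosage, dtype=float).T  # samples x candidates
    Xm = np.asarray(cis_beta, dtype=float).T

    if Xg.shape[1] == 0:
        r2_seq, seq_resid = 0.0, y - y.mean()
    else:
        pred_seq = _cv_predict(y, Xg, k_features, folds, rng)
        r2_seq = _pooled_r2(y, pred_seq)
        seq_resid = y - pred_seq
    if Xm.shape[1] == 0:
        return VariancePartition(r2_seq, 0.0, 0.0)
    pred_meth = _cv_predict(y, Xm, k_features, folds, rng)
    r2_meth = _pooled_r2(y, pred_meth)
    pred_mgs = _cv_predict(seq_resid, Xm, k_features, folds, rng)
    r2_mgs = _pooled_r2(seq_resid, pred_mgs)
    return VariancePartition(r2_seq, r2_meth, r2_mgs)


def independent_fraction(r2_meth: float, r2_meth_given_seq: float) -> float:
    """Share of methylation-explained variance independent of sequence."""
    if r2_meth <= 0:
        return math.nan
    return min(r2_meth_given_seq / r2_meth, 1.0)


def proliferation_vector(marker_expression: np.ndarray) -> np.ndarray:
    """First principal component scores of the proliferation-marker genes.

    ``marker_expression`` is a marker-gene x sample matrix; the returned
    vector scores each sample on the leading component of covariation.
    """
    if marker_expression.shape[0] < 2:
        raise ValidationError("need >= 2 marker genes")
    centered = marker_expression - marker_expression.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def proliferation_variance(
    target_values: np.ndarray, vector: np.ndarray
) -> float:
    """Cumulative fraction of target-set variance explained by the vector.

    Each target row is regressed on the proliferation vector; the explained
    fraction pools residual and original variance across rows (zero-variance
    rows are skipped and logged).
    """
    vector = np.asarray(vector, dtype=float)
    vc = vector - vector.mean()
    denom = float(vc @ vc)
    total_var = 0.0
    resid_var = 0.0
    for row in np.atleast_2d(np.asarray(target_values, dtype=float)):
        yc = row - row.mean()
        v = float(yc @ yc)
        if v == 0:
            logger.info("skipping zero-variance target row")
            continue
        slope = float(vc @ yc) / denom
        r = yc - slope * vc
        total_var += v
        resid_var += float(r @ r)
    if total_var == 0:
        return math.nan
    return 1.0 - resid_var / total_var


@dataclass
class EnrichmentResult:
    term: str
    p_value: float
    p_adjusted: float
    fold_enrichment: float
    n_test_with_term: int
    n_background_with_term: int


def term_enrichment(
    test_set: set[str],
    background_set: set[str],
    term_annotations: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Fisher's exact test and fold enrichment per annotation term.

    Fold enrichment is the proportion of test-set genes with the term
    divided by the proportion of background genes with the term. P-values
    are Benjamini-Hochberg adjusted across terms.
    """
    if not test_set <= background_set:
        raise ValidationError("test set must be a subset of the background")
    terms: dict[str, set[str]] = {}
    for gene, gene_terms in term_annotations.items():
        if gene not in background_set:
            continue
        for t in gene_terms:
            terms.setdefault(t, set()).add(gene)
    results = []
    n_test = len(test_set)
    n_bg = len(background_set)
    for term, members in sorted(terms.items()):
        a = len(test_set & members)  # test with term
        b = n_test - a
        c = len(members) - a  # non-test with term
        d = (n_bg - n_test) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        prop_bg = len(members) / n_bg
        fold = (a / n_test) / prop_bg if n_test and prop_bg else math.nan
        results.append(
            EnrichmentResult(term, float(p), math.nan, fold, a, len(members))
        )
    if results:
        adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, padj in zip(results, adjusted):
            r.p_adjusted = float(padj)
    return results
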