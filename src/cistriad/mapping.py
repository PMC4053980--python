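"""Cis-association mapping with a pooled permutation null and empirical FDR.

One engine serves four analyses that differ only in what the feature and
locus are:

====================  =======================  ====================
mode                  feature                  locus
====================  =======================  ====================
``mqtl``              CpG beta values          SNP dosages
``eqtl``              gene expression          SNP dosages
``aeqtl``             aeRegion allelic scores  SNP dosages
``methexpr``          gene expression          CpG beta values
====================  =======================  ====================

Feature-locus pairs are formed inside a cis window (the feature body plus
250 kb on either side; SNP loci additionally require minor allele frequency
above 10%). The statistic is Spearman's rank correlation. The null is built
by permuting each feature's values across individuals and repeating the full
analysis; |rho| values are pooled over pairs and replicates, empirical
p-values and the FDR-controlling |rho| cutoff are read off that pool.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AeRegion,
    CpGProbe,
    GeneModel,
    GenomicInterval,
    SnpLocus,
    ValidationError,
)

DEFAULT_WINDOW_BP = 250_000
DEFAULT_MAF_MIN = 0.10
DEFAULT_MIN_INFORMATIVE = 10


def spearman_rho(x: np.ndarray, y: np.ndarray, min_n: int = 4) -> tuple[float, int]:
    """Spearman correlation on pairwise-complete entries.

    Mid-ranks (average ranks for ties) are Pearson-correlated; genotype
    vectors are ternary so ties are the norm. Returns ``(nan, n)`` when a
    ranked vector has zero variance or fewer than ``min_n`` complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        return math.nan, n
    rx = stats.rankdata(x[mask])
    ry = stats.rankdata(y[mask])
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return math.nan, n
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return rho, n


def spearman_pvalue_t(rho: float, n: int) -> float:
    """Two-sided asymptotic p-value for Spearman's rho (Student t, n-2 df)."""
    if n < 4:
        raise ValidationError("spearman_pvalue_t needs n >= 4")
    if abs(rho) >= 1:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _feature_span(feature) -> tuple[str, int, int, str]:
    """(chrom, start, end, id) of a feature's anchor interval (half-open)."""
    if isinstance(feature, CpGProbe):
        return feature.chrom, feature.position, feature.position + 1, feature.probe_id
    if isinstance(feature, GeneModel):
        return feature.chrom, feature.start, feature.end, feature.gene_id
    if isinstance(feature, AeRegion):
        return feature.chrom, feature.start, feature.end, feature.region_id
    if isinstance(feature, GenomicInterval):
        return feature.chrom, feature.start, feature.end, feature.name or ""
    raise ValidationError(f"unsupported feature type {type(feature).__name__}")


def _locus_point(locus) -> tuple[str, int, str, float | None]:
    if isinstance(locus, SnpLocus):
        return locus.chrom, locus.position, locus.snp_id, locus.maf
    if isinstance(locus, CpGProbe):
        return locus.chrom, locus.position, locus.probe_id, None
    raise ValidationError(f"unsupported locus type {type(locus).__name__}")


MODES = ("mqtl", "eqtl", "aeqtl", "methexpr")


def build_cis_pairs(
    features,
    loci,
    mode: str,
    window: int = DEFAULT_WINDOW_BP,
    maf_min: float = DEFAULT_MAF_MIN,
) -> pd.DataFrame:
    """Enumerate feature-locus pairs within the cis window.

    A locus pairs with a feature when its position lies inside the feature's
    interval or within ``window`` bp of either boundary (closed at exactly
    ``window``). Distance is 0 inside the feature, else base pairs to the
    nearest feature boundary. SNP loci below ``maf_min`` are excluded in the
    three genotype modes; the methylation-expression mode takes CpG loci and
    applies no frequency filter.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    pts = [_locus_point(l) for l in loci]
    locus_ok = np.array(
        [
            (maf is None or mode == "methexpr" or maf > maf_min)
            for (_, _, _, maf) in pts
        ]
    )
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for (c, _, _, _) in pts}:
        idx = np.array(
            [k for k, (c, _, _, _) in enumerate(pts) if c == chrom and locus_ok[k]],
            dtype=int,
        )
        positions = np.array([pts[k][1] for k in idx])
        order = np.argsort(positions, kind="mergesort")
        by_chrom[chrom] = (idx[order], positions[order])

    rows = []
    skipped_chrom = 0
    for fi, feature in enumerate(features):
        chrom, start, end, fid = _feature_span(feature)
        if chrom not in by_chrom:
            skipped_chrom += 1
            continue
        idx, positions = by_chrom[chrom]
        lo, hi = start - window, (end - 1) + window
        a = np.searchsorted(positions, lo, side="left")
        b = np.searchsorted(positions, hi, side="right")
        for k in range(a, b):
            li = idx[k]
            pos = positions[k]
            distance = max(0, start - pos, pos - (end - 1))
            rows.append((fi, li, fid, pts[li][2], distance))
    pairs = pd.DataFrame(
        rows, columns=["feature_idx", "locus_idx", "feature_id", "locus_id", "distance_bp"]
    )
    pairs.attrs["mode"] = mode
    pairs.attrs["window"] = window
    pairs.attrs["n_skipped_unknown_chrom"] = skipped_chrom
    return pairs


@dataclass
class NullDistribution:
    """Pooled permutation null of |rho| values."""

    values: np.ndarray  # sorted ascending
    n_permutations: int
    n_pairs_per_replicate: int
    seed: int | None
    n_incomputable: int = 0

    def tail_count(self, c: float | np.ndarray) -> np.ndarray:
        return self.values.size - np.searchsorted(self.values, c, side="left")


@dataclass
class AssociationResult:
    """Cis-mapping output: per-pair statistics plus threshold provenance."""

    pairs: pd.DataFrame
    rho_cutoff: float
    p_cutoff: float
    fdr: float
    mode: str
    null: NullDistribution
    n_dropped_pairs: int = 0

    @property
    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"].astype(bool)]

    def significant_loci(self) -> set[str]:
        return set(self.significant["locus_id"])

    def significant_features(self) -> set[str]:
        return set(self.significant["feature_id"])


def _zranks(x: np.ndarray) -> np.ndarray | None:
    r = stats.rankdata(x)
    s = r.std()
    if s == 0:
        return None
    return (r - r.mean()) / s


def permutation_fdr_map(
    feature_values: np.ndarray,
    locus_values: np.ndarray,
    pairs: pd.DataFrame,
    fdr: float = 0.05,
    n_permutations: int = 10,
    seed: int | None = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    mode: str | None = None,
) -> AssociationResult:
    """Map features to loci and flag pairs at an empirical FDR.

    For every pair the observed Spearman |rho| is computed on pairwise-
    complete samples. Each permutation replicate shuffles every feature's
    observed values across individuals (independently per feature, keeping
    the missingness pattern) and repeats the full analysis; null |rho| are
    pooled over pairs and replicates. Then

    - empirical p(pair) = (1 + #null >= |rho|) / (1 + #null),
    - FDR(c) = (mean null count >= c per replicate) / (observed count >= c),
    - the |rho| cutoff is the smallest observed value with FDR <= ``fdr``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    feature_values = np.asarray(feature_values, dtype=float)
    locus_values = np.asarray(locus_values, dtype=float)
    mode = mode or pairs.attrs.get("mode", "generic")
    rng = np.random.default_rng(seed)

    feature_groups = pairs.groupby("feature_idx", sort=True)
    obs_rho = np.full(len(pairs), np.nan)
    obs_n = np.zeros(len(pairs), dtype=int)
    null_chunks: list[np.ndarray] = []
    n_dropped = 0
    n_incomputable_null = 0

    for fidx, group in feature_groups:
        frow = feature_values[fidx]
        fmask = np.isfinite(frow)
        rows = group.index.to_numpy()
        lidx = group["locus_idx"].to_numpy()
        lblock = locus_values[lidx]
        lmask = np.isfinite(lblock)
        shared = lmask.all(axis=0)
        if (fmask & shared).sum() == fmask.sum() and fmask.sum() >= min_informative:
            # all loci observed wherever the feature is: one common mask
            m = fmask
            fz = _zranks(frow[m])
            if fz is None:
                n_dropped += len(rows)
                continue
            lz = np.empty((len(rows), m.sum()))
            keep = np.ones(len(rows), dtype=bool)
            for k in range(len(rows)):
                z = _zranks(lblock[k, m])
                if z is None:
                    keep[k] = False
                else:
                    lz[k] = z
            nm = m.sum()
            obs_rho[rows[keep]] = (lz[keep] @ fz) / nm
            obs_n[rows[keep]] = nm
            n_dropped += int((~keep).sum())
            if keep.any():
                perms = np.column_stack(
                    [rng.permutation(fz) for _ in range(n_permutations)]
                )
                null_chunks.append(np.abs((lz[keep] @ perms) / nm).ravel())
            else:
                n_incomputable_null += n_permutations * len(rows)
        else:
            # per-pair masks (e.g. aeRegion scores with per-sample missingness)
            for k, row in enumerate(rows):
                x, y = frow, lblock[k]
                m = np.isfinite(x) & np.isfinite(y)
                nm = int(m.sum())
                if nm < min_informative:
                    n_dropped += 1
                    continue
                fz = _zranks(x[m])
                lzk = _zranks(y[m])
                if fz is None or lzk is None:
                    n_dropped += 1
                    continue
                obs_rho[row] = float(lzk @ fz) / nm
                obs_n[row] = nm
                perms = np.column_stack(
                    [rng.permutation(fz) for _ in range(n_permutations)]
                )
                null_chunks.append(np.abs((lzk @ perms) / nm))

    null_values = (
        np.sort(np.concatenate(null_chunks)) if null_chunks else np.array([])
    )
    computable = np.isfinite(obs_rho)
    n_pairs_rep = int(computable.sum())
    null = NullDistribution(
        values=null_values,
        n_permutations=n_permutations,
        n_pairs_per_replicate=n_pairs_rep,
        seed=seed,
        n_incomputable=n_incomputable_null,
    )

    abs_rho = np.abs(obs_rho)
    n_null = null_values.size
    p_emp = np.full(len(pairs), np.nan)
    p_emp[computable] = (1.0 + null.tail_count(abs_rho[computable])) / (1.0 + n_null)

    rho_cutoff, p_cutoff = select_rho_cutoff(abs_rho[computable], null, fdr)
    with np.errstate(invalid="ignore"):
        significant = abs_rho >= rho_cutoff

    out = pairs.copy()
    out["rho"] = obs_rho
    out["p_empirical"] = p_emp
    out["n_informative"] = obs_n
    out["significant"] = significant
    return AssociationResult(
        pairs=out,
        rho_cutoff=rho_cutoff,
        p_cutoff=p_cutoff,
        fdr=fdr,
        mode=mode,
        null=null,
        n_dropped_pairs=n_dropped,
    )


def select_rho_cutoff(
    abs_rho: np.ndarray, null: NullDistribution, fdr: float
) -> tuple[float, float]:
    """Smallest observed |rho| with tail-ratio FDR <= the requested level."""
    if abs_rho.size == 0 or null.values.size == 0:
        return math.inf, 0.0
    candidates = np.unique(abs_rho)  # ascending
    obs_sorted = np.sort(abs_rho)
    obs_count = abs_rho.size - np.searchsorted(obs_sorted, candidates, side="left")
    null_mean = null.tail_count(candidates) / null.n_permutations
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at = np.where(obs_count > 0, null_mean / obs_count, np.inf)
    passing = np.flatnonzero(fdr_at <= fdr)
    if passing.size == 0:
        return math.inf, 0.0
    cutoff = float(candidates[passing[0]])
    p_cutoff = float(
        (1.0 + null.tail_count(np.array([cutoff]))[0]) / (1.0 + null.values.size)
    )
    return cutoff, p_cutoff


def exact_spearman_null(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|rho| under all n! pairings of y against x (exact null, n <= 7)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 7:
        raise ValidationError("exact enumeration supported for n <= 7 only")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = ry - ry.mean()
    sy = ry.std()
    out = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(range(n))):
        out[i] = abs(float(zx @ zy[list(perm)]) / (n * sy))
    return out


def ld_pruned_qq(
    result: AssociationResult,
    dosage: np.ndarray,
    r2_cutoff: float = 0.8,
    distance_bins: list[int] | None = None,
) -> pd.DataFrame:
    """Greedy per-feature LD pruning of pairs for distance-binned QQ data.

    Per feature: take the most strongly associated remaining locus, emit its
    p-value into the bin of its distance, remove loci in linkage
    disequilibrium with it (squared Pearson correlation of dosages above the
    cutoff), repeat until no locus remains. The returned table carries the
    expected uniform quantile per emitted p within its bin. With missing
    dosages the R^2 uses per-locus standardization over each locus's own
    observed samples (exact for complete dosage matrices).
    """
    if distance_bins is None:
        distance_bins = [0, 1_000, 5_000, 25_000, 100_000, 250_001]
    emitted = []
    for fid, group in result.pairs.groupby("feature_id", sort=False):
        group = group[np.isfinite(group["rho"])]
        remaining = group.sort_values(
            ["p_empirical", "rho"], ascending=[True, False], kind="mergesort"
        )
        lidx = remaining["locus_idx"].to_numpy(dtype=int)
        rows = dosage[lidx]
        # pairwise-complete standardization; NaNs contribute zero so the dot
        # product below is the correlation over mutually observed samples
        finite = np.isfinite(rows)
        if finite.all():
            mean = rows.mean(axis=1, keepdims=True)
            sd = rows.std(axis=1, keepdims=True)
            sd[sd == 0] = np.inf
            z = (rows - mean) / sd / np.sqrt(rows.shape[1])
        else:
            z = np.zeros_like(rows)
            for k in range(rows.shape[0]):
                m = finite[k]
                col = rows[k, m]
                s = col.std()
                if s > 0 and m.sum() >= 3:
                    z[k, m] = (col - col.mean()) / s / np.sqrt(m.sum())
        alive = np.arange(len(remaining))
        while alive.size:
            best_pos = alive[0]
            best = remaining.iloc[best_pos]
            emitted.append(
                (fid, best["locus_id"], best["p_empirical"], best["distance_bp"])
            )
            r2 = (z[alive] @ z[best_pos]) ** 2
            alive = alive[1:][r2[1:] <= r2_cutoff]
    table = pd.DataFrame(
        emitted, columns=["feature_id", "locus_id", "p_empirical", "distance_bp"]
    )
    if table.empty:
        table["bin"] = []
        table["expected_p"] = []
        return table
    table["bin"] = pd.cut(
        table["distance_bp"], bins=distance_bins, right=False, include_lowest=True
    )
    table["expected_p"] = np.nan
    for _, idx in table.groupby("bin", observed=True).groups.items():
        ps = table.loc[idx, "p_empirical"]
        ranks = stats.rankdata(ps)
        table.loc[idx, "expected_p"] = (ranks - 0.5) / len(ps)
    return table
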