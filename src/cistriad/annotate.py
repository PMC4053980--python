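"""Genomic-context annotation of CpG probes and loci.

Classifiers follow the conventions of the 450K literature: a probe is "TSS"
when within 1,500 bp of any transcription start site (closed boundary),
"body" when inside an annotated transcript but not near a TSS, else
"intergenic". Island context uses the Illumina definitions (shore < 2 kb
from an island, shelf 2-4 kb, open sea beyond). Methylation class splits the
bimodal beta distribution at mean beta 0.3 (hypomethylated) and 0.7
(hypermethylated). Modality of a probe's inter-individual beta distribution
is the number of kernel-density modes on 100 bins whose height reaches 1.2
times the average bin density.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import CpGProbe, GeneModel, GenomicInterval, MarkTrackSet, ValidationError

TSS_FLANK_BP = 1_500
SHORE_BP = 2_000
SHELF_BP = 4_000
HYPO_MAX_BETA = 0.3
HYPER_MIN_BETA = 0.7
MODE_HEIGHT_FACTOR = 1.2
N_DENSITY_BINS = 100


def classify_position(
    chrom: str, position: int, genes: list[GeneModel], tss_flank: int = TSS_FLANK_BP
) -> str:
    """Label a point as 'TSS', 'body' or 'intergenic' relative to genes."""
    in_body = False
    for gene in genes:
        if gene.chrom != chrom:
            continue
        if abs(position - gene.tss) <= tss_flank:
            return "TSS"
        if gene.start <= position < gene.end:
            in_body = True
    return "body" if in_body else "intergenic"


def classify_island_context(
    chrom: str, position: int, islands: list[GenomicInterval]
) -> str:
    """Label a point as island / shore / shelf / open_sea.

    Distance to an island is 0 inside it; shore is (0, 2 kb), shelf the
    closed band [2 kb, 4 kb], open sea beyond 4 kb (or no island on the
    chromosome).
    """
    best = None
    for island in islands:
        if island.chrom != chrom:
            continue
        if island.start <= position < island.end:
            return "island"
        d = island.start - position if position < island.start else position - (island.end - 1)
        best = d if best is None else min(best, d)
    if best is None or best > SHELF_BP:
        return "open_sea"
    if best < SHORE_BP:
        return "shore"
    return "shelf"


def methylation_class(mean_beta: float) -> str:
    """hypo (< 0.3), hyper (> 0.7) or intermediate mean methylation."""
    if not 0.0 <= mean_beta <= 1.0:
        raise ValidationError(f"mean beta must lie in [0, 1], got {mean_beta}")
    if mean_beta < HYPO_MAX_BETA:
        return "hypo"
    if mean_beta > HYPER_MIN_BETA:
        return "hyper"
    return "intermediate"


def mark_overlap_counts(
    chrom: str, position: int, marks: MarkTrackSet
) -> dict[str, int]:
    """Per mark, the number of cell lines with an interval covering the point.

    A locus "has" a mark when the count is at least one; the count itself
    supports stratifying by how many of the assayed lines carry the mark.
    """
    counts: dict[str, int] = {}
    for mark, lines in marks.items():
        c = 0
        for intervals in lines.values():
            if any(iv.contains(chrom, position) for iv in intervals):
                c += 1
        counts[mark] = c
    return counts


def count_modes(
    values: np.ndarray,
    min_values: int = 10,
    bandwidth: float | str = "silverman",
) -> int:
    """Count modes of a beta-value sample via kernel density on 100 bins.

    A Gaussian kernel density (Silverman bandwidth on the original sample by
    default; the sample is reflected at the [0, 1] support boundaries to
    correct edge bias) is evaluated at 100 equal-width bin centers; a mode is
    a strict local maximum whose density reaches at least 1.2 times the
    average bin density. ``bandwidth`` may also be a fixed kernel width.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_values:
        raise ValidationError(f"count_modes needs >= {min_values} values")
    centers = (np.arange(N_DENSITY_BINS) + 0.5) / N_DENSITY_BINS
    if values.std() == 0:
        density = np.zeros(N_DENSITY_BINS)
        density[int(np.clip(values[0] * N_DENSITY_BINS, 0, 99))] = 1.0
    else:
        if bandwidth == "silverman":
            # Silverman's rule on the original sample; the reflected copies
            # only correct boundary bias and must not widen the bandwidth
            iqr = np.subtract(*np.percentile(values, [75, 25]))
            spread = min(values.std(ddof=1), iqr / 1.34) if iqr > 0 else values.std(ddof=1)
            h = 0.9 * spread * values.size ** (-0.2)
        else:
            h = float(bandwidth)
        reflected = np.concatenate([values, -values, 2.0 - values])
        kde = stats.gaussian_kde(
            reflected, bw_method=h / reflected.std(ddof=1)
        )
        density = kde(centers)
    mean_density = density.mean()
    if mean_density == 0:
        return 0
    n_modes = 0
    for i in range(N_DENSITY_BINS):
        left_ok = i == 0 or density[i] > density[i - 1]
        right_ok = i == N_DENSITY_BINS - 1 or density[i] > density[i + 1]
        if left_ok and right_ok and density[i] >= MODE_HEIGHT_FACTOR * mean_density:
            n_modes += 1
    return n_modes


def annotate_cpgs(
    probes: list[CpGProbe],
    beta: np.ndarray,
    genes: list[GeneModel],
    islands: list[GenomicInterval],
    marks: MarkTrackSet | None = None,
    count_modality: bool = True,
) -> pd.DataFrame:
    """Full per-probe context table (position, island, methylation class,
    mark overlap counts, number of modes)."""
    rows = []
    mean_beta = np.nanmean(beta, axis=1)
    for k, probe in enumerate(probes):
        row = {
            "probe_id": probe.probe_id,
            "chrom": probe.chrom,
            "position": probe.position,
            "probe_type": probe.probe_type,
            "mean_beta": mean_beta[k],
            "position_class": classify_position(probe.chrom, probe.position, genes),
            "island_class": classify_island_context(
                probe.chrom, probe.position, islands
            ),
            "methylation_class": methylation_class(float(mean_beta[k])),
        }
        if marks:
            for mark, count in mark_overlap_counts(
                probe.chrom, probe.position, marks
            ).items():
                row[f"n_lines_{mark}"] = count
        if count_modality:
            row["n_modes"] = count_modes(beta[k])
        rows.append(row)
    return pd.DataFrame(rows)


def tss_profile(
    probes: list[CpGProbe],
    stat: np.ndarray,
    genes: list[GeneModel],
    gene_quartiles: dict[str, int],
    window: int = 201,
) -> pd.DataFrame:
    """Running median of a per-probe statistic against signed TSS distance.

    Each probe is assigned to the gene with the nearest TSS (ties broken by
    lower gene id); the signed distance is strand-oriented (negative =
    upstream). Within each expression quartile, probes are ordered by signed
    distance and the statistic is smoothed with a centered running median of
    ``window`` probes.
    """
    rows = []
    for k, probe in enumerate(probes):
        best: tuple[int, str, int] | None = None
        for gene in genes:
            if gene.chrom != probe.chrom:
                continue
            d = probe.position - gene.tss
            if gene.strand == "-":
                d = -d
            key = (abs(d), gene.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (abs(d), gene.gene_id, d)
        if best is None:
            continue
        rows.append(
            {
                "probe_id": probe.probe_id,
                "gene_id": best[1],
                "signed_distance": best[2],
                "stat": stat[k],
                "quartile": gene_quartiles.get(best[1]),
            }
        )
    table = pd.DataFrame(rows).dropna(subset=["quartile"])
    if table.empty:
        table["running_median"] = []
        return table
    pieces = []
    for _, sub in table.groupby("quartile"):
        sub = sub.sort_values(["signed_distance", "probe_id"], kind="mergesort").copy()
        sub["running_median"] = (
            sub["stat"].rolling(window, center=True, min_periods=1).median()
        )
        pieces.append(sub)
    return pd.concat(pieces, ignore_index=True)
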