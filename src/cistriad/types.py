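"""Shared domain types for the fibroblast multi-omic cis-mapping pipeline.

Coordinates are BED-style throughout: 0-based, half-open intervals; point
features (SNPs, CpG probes) carry a single 0-based position. Distances are
absolute base-pair differences. Matrices are feature-by-sample numpy arrays
with NaN marking missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """An input violates a domain-type invariant (never silently repaired)."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the coordinates the cis analyses need.

    ``tss``/``tes`` are the transcription start/end sites; the gene body is
    the half-open interval between them regardless of strand.
    """

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss == self.tes:
            raise ValidationError(f"gene {self.gene_id}: tss must differ from tes")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_id)


@dataclass(frozen=True)
class CpGProbe:
    probe_id: str
    chrom: str
    position: int
    probe_type: str = "II"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"probe {self.probe_id}: position must be >= 0")
        if self.probe_type not in ("I", "II"):
            raise ValidationError(
                f"probe {self.probe_id}: probe_type must be 'I' or 'II'"
            )


@dataclass(frozen=True)
class SnpLocus:
    snp_id: str
    chrom: str
    position: int
    maf: float = 0.25

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"snp {self.snp_id}: position must be >= 0")
        if not 0.0 <= self.maf <= 0.5:
            raise ValidationError(
                f"snp {self.snp_id}: maf must lie in [0, 0.5], got {self.maf}"
            )


@dataclass
class SampleSet:
    """Ordered cohort sample ids plus per-assay availability masks.

    Assays may cover subsets of the cohort (e.g. expression measured on 58
    of 62 individuals); a mask is a boolean vector aligned with
    ``sample_ids``.
    """

    sample_ids: list[str]
    assay_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids must be unique")
        for assay, mask in self.assay_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (len(self.sample_ids),):
                raise ValidationError(
                    f"assay mask '{assay}' length {mask.size} != "
                    f"{len(self.sample_ids)} samples"
                )
            self.assay_masks[assay] = mask

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def mask(self, assay: str) -> np.ndarray:
        if assay in self.assay_masks:
            return self.assay_masks[assay]
        return np.ones(self.n, dtype=bool)


def _check_alignment(name: str, values: np.ndarray, n_features: int, n_samples: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (n_features, n_samples):
        raise ValidationError(
            f"{name}: matrix shape {values.shape} does not match "
            f"{n_features} features x {n_samples} samples"
        )
    return values


@dataclass
class GenotypeMatrix:
    """SNP-by-sample dosage matrix (minor-allele counts, real dosages allowed)."""

    loci: list[SnpLocus]
    samples: SampleSet
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = _check_alignment(
            "genotype", self.dosage, len(self.loci), self.samples.n
        )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages must lie in [0, 2]")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.loci]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.loci])

    def realized_maf(self) -> np.ndarray:
        freq = np.nanmean(self.dosage, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class MethylationMatrix:
    """CpG-by-sample beta values (methylated fraction, in [0, 1] or missing)."""

    probes: list[CpGProbe]
    samples: SampleSet
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = _check_alignment(
            "methylation", self.beta, len(self.probes), self.samples.n
        )
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.probes])


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression levels (finite or missing)."""

    genes: list[GeneModel]
    samples: SampleSet
    level: np.ndarray

    def __post_init__(self) -> None:
        self.level = _check_alignment(
            "expression", self.level, len(self.genes), self.samples.n
        )

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class AlleleRatioTrack:
    """Per-SNP log2 allelic expression ratios, defined on heterozygous entries.

    ``raw_ratio`` holds the measured log2(allele A / allele B) per sample at
    its heterozygous SNPs (NaN elsewhere); ``smoothed_ratio`` is filled by the
    left-to-right HMM and shares the missingness pattern of the raw track.
    """

    loci: list[SnpLocus]
    samples: SampleSet
    raw_ratio: np.ndarray
    smoothed_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_ratio = _check_alignment(
            "allele ratio", self.raw_ratio, len(self.loci), self.samples.n
        )
        pos = [s.position for s in self.loci]
        chroms = [s.chrom for s in self.loci]
        for i in range(1, len(pos)):
            if chroms[i] == chroms[i - 1] and pos[i] <= pos[i - 1]:
                raise ValidationError(
                    "allele ratio loci must be strictly increasing within a chromosome"
                )
        if self.smoothed_ratio is not None:
            self.smoothed_ratio = _check_alignment(
                "smoothed allele ratio",
                self.smoothed_ratio,
                len(self.loci),
                self.samples.n,
            )
            if not np.array_equal(
                np.isnan(self.smoothed_ratio), np.isnan(self.raw_ratio)
            ):
                raise ValidationError(
                    "smoothed track must share the raw track's missingness pattern"
                )

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.loci]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.loci])


@dataclass
class AeRegion:
    """A maximal run of >= 2 consecutive same-sign allelically expressed SNPs."""

    region_id: str
    chrom: str
    start: int
    end: int
    member_snp_ids: list[str]
    sign: int
    sample_scores: np.ndarray  # per-sample mean smoothed ratio over members

    def __post_init__(self) -> None:
        if len(self.member_snp_ids) < 2:
            raise ValidationError(
                f"aeRegion {self.region_id} needs >= 2 member SNPs"
            )
        if self.sign not in (-1, 1):
            raise ValidationError("aeRegion sign must be +1 or -1")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.region_id)


# mark name -> cell line -> intervals
MarkTrackSet = dict[str, dict[str, list[GenomicInterval]]]
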