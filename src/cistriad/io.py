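"""Readers and writers for the plain-text interchange formats.

BED for intervals (0-based, half-open), TSV for matrices (header row =
sample ids, first column = feature ids, empty cells = missing) and for
coordinate tables. Loaders validate and reject; they never repair.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AlleleRatioTrack,
    CpGProbe,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    GenotypeMatrix,
    MethylationMatrix,
    SampleSet,
    SnpLocus,
    ValidationError,
)


def load_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3/BED4 file into intervals, preserving input order."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_intervals_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate feature id '{dup}'")
    values = frame.where(frame != "", other=np.nan).astype(float)
    return values


def _default_samples(sample_ids: list[str]) -> SampleSet:
    return SampleSet(sample_ids=list(sample_ids))


def _stub_snps(ids: list[str]) -> list[SnpLocus]:
    return [SnpLocus(i, "un", k, 0.25) for k, i in enumerate(ids)]


def load_matrix_tsv(path: str | Path, kind: str, coords: pd.DataFrame | None = None):
    """Load a feature x sample TSV into its typed matrix.

    ``kind`` is one of ``genotype``, ``beta``, ``expression``, ``ae_ratio``.
    ``coords`` optionally supplies feature coordinates (indexed by feature id
    with columns ``chrom`` and ``position`` — plus ``tes``/``strand`` for
    genes, ``maf`` for SNPs, ``probe_type`` for CpGs). Without it, features
    are placed in file order on pseudo-chromosome "un".
    """
    values = _read_tsv_matrix(path)
    ids = list(values.index)
    samples = _default_samples(list(values.columns))
    mat = values.to_numpy(dtype=float)

    def coord(fid: str, col: str, default):
        if coords is None or col not in coords.columns:
            return default
        return coords.loc[fid, col]

    if kind == "genotype":
        loci = [
            SnpLocus(
                fid,
                str(coord(fid, "chrom", "un")),
                int(coord(fid, "position", k)),
                float(coord(fid, "maf", 0.25)),
            )
            for k, fid in enumerate(ids)
        ]
        return GenotypeMatrix(loci, samples, mat)
    if kind == "beta":
        probes = [
            CpGProbe(
                fid,
                str(coord(fid, "chrom", "un")),
                int(coord(fid, "position", k)),
                str(coord(fid, "probe_type", "II")),
            )
            for k, fid in enumerate(ids)
        ]
        return MethylationMatrix(probes, samples, mat)
    if kind == "expression":
        genes = [
            GeneModel(
                fid,
                str(coord(fid, "chrom", "un")),
                int(coord(fid, "position", 2 * k)),
                int(coord(fid, "tes", 2 * k + 1)),
                str(coord(fid, "strand", "+")),
            )
            for k, fid in enumerate(ids)
        ]
        return ExpressionMatrix(genes, samples, mat)
    if kind == "ae_ratio":
        if coords is not None:
            loci = [
                SnpLocus(
                    fid,
                    str(coord(fid, "chrom", "un")),
                    int(coord(fid, "position", k)),
                    float(coord(fid, "maf", 0.25)),
                )
                for k, fid in enumerate(ids)
            ]
        else:
            loci = _stub_snps(ids)
        return AlleleRatioTrack(loci, samples, mat)
    raise ValueError(f"unknown matrix kind '{kind}'")


def write_matrix_tsv(feature_ids, sample_ids, values: np.ndarray, path: str | Path) -> None:
    """Write a feature x sample matrix; NaN becomes an empty cell."""
    frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", na_rep="")


def load_snp_table(path: str | Path) -> list[SnpLocus]:
    t = pd.read_csv(path, sep="\t")
    return [
        SnpLocus(str(r.snp_id), str(r.chrom), int(r.position), float(r.maf))
        for r in t.itertuples()
    ]


def load_gene_table(path: str | Path) -> list[GeneModel]:
    t = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), int(r.tes), str(r.strand))
        for r in t.itertuples()
    ]


def load_cpg_table(path: str | Path) -> list[CpGProbe]:
    t = pd.read_csv(path, sep="\t")
    return [
        CpGProbe(str(r.probe_id), str(r.chrom), int(r.position), str(r.probe_type))
        for r in t.itertuples()
    ]


def write_snp_table(loci: list[SnpLocus], path: str | Path) -> None:
    pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in loci],
            "chrom": [s.chrom for s in loci],
            "position": [s.position for s in loci],
            "maf": [s.maf for s in loci],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "tes": [g.tes for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def write_cpg_table(probes: list[CpGProbe], path: str | Path) -> None:
    pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "chrom": [p.chrom for p in probes],
            "position": [p.position for p in probes],
            "probe_type": [p.probe_type for p in probes],
        }
    ).to_csv(path, sep="\t", index=False)


ASSOCIATION_COLUMNS = [
    "feature_id",
    "locus_id",
    "rho",
    "p_empirical",
    "distance_bp",
    "significant",
]


def write_association_table(result, path: str | Path) -> None:
    """Write an AssociationResult's pair table with threshold provenance.

    Header comment lines record the FDR level, permutation count, seed and
    realized rho/p cutoffs so the table is self-describing.
    """
    meta = {
        "mode": result.mode,
        "fdr": result.fdr,
        "n_permutations": result.null.n_permutations,
        "seed": result.null.seed,
        "rho_cutoff": result.rho_cutoff,
        "p_cutoff": result.p_cutoff,
    }
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        table = result.pairs[ASSOCIATION_COLUMNS]
        buf = _io.StringIO()
        table.to_csv(buf, sep="\t", index=False)
        fh.write(buf.getvalue())


def read_association_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            key, _, val = line[2:].strip().partition("=")
            meta[key] = val
        else:
            body_start = i
            break
    table = pd.read_csv(
        _io.StringIO("".join(lines[body_start:])), sep="\t"
    )
    return table, meta
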