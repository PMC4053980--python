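"""Normalization and variance filtering applied ahead of cis mapping.

Beta values are quantile-normalized separately per probe type (type I and
type II chemistries have different beta distributions), against a reference
distribution built from the per-probe means. Expression is normalized with
the same rule. Features are then restricted to the most variable fraction
(top 25% of CpG probes, top 50% of genes by default usage).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import ValidationError


def quantile_normalize(
    values: np.ndarray,
    groups: np.ndarray | None = None,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Quantile-normalize columns within each feature group.

    Within a group, the reference distribution defaults to the sorted vector
    of per-feature mean values; each sample column's entries are replaced by
    the reference value at their within-column rank. Ties receive the mean
    of the tied reference slots.

    Normalization against an explicitly supplied ``reference`` is exactly
    idempotent. With the default (data-derived) reference, re-application
    recomputes the reference from the normalized values, which in general
    shifts it slightly; identical columns are an exact fixed point.

    Parameters
    ----------
    values : (n_features, n_samples) array, no missing entries
    groups : per-feature group labels (e.g. probe type); None = one group
    reference : sorted reference distribution (only without ``groups``)
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValidationError("quantile_normalize requires complete data")
    out = np.empty_like(values)
    if groups is None:
        groups = np.zeros(values.shape[0], dtype=int)
    elif reference is not None:
        raise ValidationError("explicit reference requires a single group")
    groups = np.asarray(groups)
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        if rows.size < 2:
            raise ValidationError(
                f"quantile normalization group '{g}' has < 2 features"
            )
        block = values[rows]
        if reference is None:
            ref = np.sort(block.mean(axis=1))
        else:
            ref = np.sort(np.asarray(reference, dtype=float))
            if ref.size != rows.size:
                raise ValidationError("reference length must match feature count")
        norm = np.empty_like(block)
        for j in range(block.shape[1]):
            norm[:, j] = _column_to_reference(block[:, j], ref)
        out[rows] = norm
    return out


def _column_to_reference(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(column, kind="mergesort")
    mapped = np.empty_like(column)
    mapped[order] = reference
    # tied input values share the mean of their reference slots
    sorted_vals = column[order]
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [column.size]))
    for s, e in zip(starts, ends):
        if e - s > 1:
            mapped[order[s:e]] = reference[s:e].mean()
    return mapped


@dataclass
class VarianceFilterResult:
    kept_ids: list[str]
    kept_index: np.ndarray
    sd: np.ndarray  # per-feature SD, input order
    cutoff: float
    fraction_kept: float


def variance_filter(
    values: np.ndarray,
    top_fraction: float,
    feature_ids: list[str] | None = None,
) -> VarianceFilterResult:
    """Keep the ``ceil(top_fraction * n)`` features with largest sample SD.

    SDs use pairwise-complete (NaN-aware) samples with ddof=1. Ties at the
    cutoff are broken by input order so the kept count is exact.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if feature_ids is None:
        feature_ids = [str(i) for i in range(n)]
    n_obs = np.sum(np.isfinite(values), axis=1)
    if (n_obs < 2).any():
        raise ValidationError("every feature needs >= 2 non-missing values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sd = np.nanstd(values, axis=1, ddof=1)
    if np.all(sd == 0):
        warnings.warn("all features constant; variance filter keeps nothing")
        return VarianceFilterResult([], np.array([], dtype=int), sd, math.inf, 0.0)
    n_keep = math.ceil(top_fraction * n)
    order = np.lexsort((np.arange(n), -sd))  # by SD desc, stable in input order
    kept = np.sort(order[:n_keep])
    cutoff = float(sd[kept].min())
    return VarianceFilterResult(
        kept_ids=[feature_ids[i] for i in kept],
        kept_index=kept,
        sd=sd,
        cutoff=cutoff,
        fraction_kept=n_keep / n,
    )


def regress_out_components(values: np.ndarray, k: int) -> np.ndarray:
    """Remove the top-k sample-space principal components from every feature.

    Rows are centered; the components are the leading right singular vectors
    of the centered matrix, and each feature's projection onto them is
    subtracted. ``k = 0`` returns the centered input.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValidationError("regress_out_components requires complete data")
    n_samples = values.shape[1]
    if k < 0:
        k = 0
    if k >= n_samples:
        raise ValidationError(f"k={k} must be < n_samples={n_samples}")
    centered = values - values.mean(axis=1, keepdims=True)
    if k == 0:
        return centered
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:k]  # (k, n_samples), orthonormal
    return centered - (centered @ components.T) @ components
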