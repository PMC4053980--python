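"""Allelic-expression smoothing, threshold calibration, and segmentation.

Raw per-SNP log2 allelic ratios (defined at heterozygous SNPs only) are
noisy; an eight-state left-to-right hidden Markov model is run along each
sample's chain of informative SNPs, and the smoothed score at a SNP is the
posterior-weighted mean of the state levels. "Left-to-right" is implemented
as banded transitions: from state i the chain may stay or move to state
i - 1 or i + 1, which lets the allelic level drift gradually along the
chromosome while discouraging isolated jumps. The high default
self-transition makes the smoother suppress single-SNP outliers (which the
permutation-calibrated threshold relies on) while still following runs of a
few consistent SNPs.

An aeSNP is a SNP whose |smoothed| score exceeds a threshold in at least a
minimum number of samples; the threshold is calibrated to a target false
discovery rate by permuting the raw ratios within each sample (destroying
the spatial runs that carry real signal), re-smoothing, and comparing null
and observed call counts. Consecutive same-sign aeSNPs form aeRegions,
scored per sample by the mean smoothed ratio over member SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AeRegion, AlleleRatioTrack, ValidationError

DEFAULT_STATE_MEANS = (-1.2, -0.8, -0.4, -0.1, 0.1, 0.4, 0.8, 1.2)


@dataclass
class HmmSpec:
    """Fixed-parameter left-to-right HMM over allelic log2-ratio levels."""

    state_means: tuple[float, ...] = DEFAULT_STATE_MEANS
    emission_sd: float = 0.15
    self_transition: float = 0.99
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means, dtype=float)
        if np.any(np.diff(means) < 0):
            raise ValidationError("state means must be non-decreasing")
        if not 0 < self.self_transition < 1:
            raise ValidationError("self-transition must lie in (0, 1)")
        self.state_means = tuple(means)
        if self.initial is None:
            self.initial = np.full(means.size, 1.0 / means.size)
        else:
            self.initial = np.asarray(self.initial, dtype=float)
            if not np.isclose(self.initial.sum(), 1.0):
                raise ValidationError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.state_means)

    def transition_matrix(self) -> np.ndarray:
        """Banded row-stochastic matrix: stay or step to an adjacent state."""
        n = self.n_states
        stay = self.self_transition
        trans = np.zeros((n, n))
        for i in range(n):
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < n]
            trans[i, i] = stay
            for j in neighbors:
                trans[i, j] = (1.0 - stay) / len(neighbors)
        return trans


def _emission_probs(obs: np.ndarray, spec: HmmSpec) -> np.ndarray:
    """(T, S) Gaussian emission densities (unnormalized constants cancel)."""
    means = np.asarray(spec.state_means)
    z = (obs[:, None] - means[None, :]) / spec.emission_sd
    return np.exp(-0.5 * z * z)


def forward_backward(obs: np.ndarray, spec: HmmSpec) -> np.ndarray:
    """Posterior state probabilities for one observation chain.

    Scaled forward-backward; returns a (T, n_states) matrix of posteriors.
    """
    obs = np.asarray(obs, dtype=float)
    T = obs.size
    if T == 0:
        return np.zeros((0, spec.n_states))
    emis = _emission_probs(obs, spec)
    trans = spec.transition_matrix()
    alpha = np.empty_like(emis)
    scale = np.empty(T)
    alpha[0] = spec.initial * emis[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * emis[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty_like(emis)
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (emis[t + 1] * beta[t + 1])) / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def smooth_allelic_ratios(
    track: AlleleRatioTrack, spec: HmmSpec | None = None
) -> AlleleRatioTrack:
    """Fill ``track.smoothed_ratio`` with posterior-mean scores per sample.

    Each sample's chain is its observed (heterozygous) loci in genome order,
    one chain per chromosome. Samples with no observed loci stay all-missing.
    """
    if spec is None:
        spec = HmmSpec()
    track.smoothed_ratio = smooth_matrix(
        track.raw_ratio, np.array([s.chrom for s in track.loci]), spec
    )
    return track


def smooth_matrix(
    raw: np.ndarray, chroms: np.ndarray, spec: HmmSpec
) -> np.ndarray:
    """HMM-smooth a loci x samples ratio matrix, chromosome by chromosome."""
    means = np.asarray(spec.state_means)
    smoothed = np.full_like(raw, np.nan)
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        block = raw[rows]
        for j in range(block.shape[1]):
            observed = np.flatnonzero(np.isfinite(block[:, j]))
            if observed.size == 0:
                continue
            post = forward_backward(block[observed, j], spec)
            smoothed[rows[observed], j] = post @ means
    return smoothed


DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 2)


def _call_counts(smoothed: np.ndarray, grid: np.ndarray, min_samples: int) -> np.ndarray:
    """Number of SNPs with |smoothed| > t in >= min_samples samples, per t."""
    mags = np.abs(smoothed)
    counts = np.empty(grid.size, dtype=int)
    for k, t in enumerate(grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            super_t = np.nansum(mags > t, axis=1)
        counts[k] = int(np.sum(super_t >= min_samples))
    return counts


@dataclass
class AeThresholdCalibration:
    threshold: float | None
    grid: np.ndarray
    observed_calls: np.ndarray
    mean_null_calls: np.ndarray
    fdr: np.ndarray
    n_permutations: int
    seed: int | None


def calibrate_ae_threshold(
    track: AlleleRatioTrack,
    target_fdr: float = 0.05,
    min_samples: int = 2,
    n_permutations: int = 10,
    seed: int | None = None,
    spec: HmmSpec | None = None,
    grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
) -> AeThresholdCalibration:
    """Pick the smallest threshold whose permutation FDR is <= the target.

    The null is built by permuting each sample's raw ratios among that
    sample's observed SNPs (within-sample permutation) and re-running the
    HMM; empirical FDR(t) = mean null call count at (t, min_samples) divided
    by the observed call count.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if spec is None:
        spec = HmmSpec()
    if track.smoothed_ratio is None:
        smooth_allelic_ratios(track, spec)
    chroms = np.array([s.chrom for s in track.loci])
    observed_calls = _call_counts(track.smoothed_ratio, grid, min_samples)

    rng = np.random.default_rng(seed)
    null_calls = np.zeros((n_permutations, grid.size), dtype=int)
    raw = track.raw_ratio
    for p in range(n_permutations):
        permuted = np.full_like(raw, np.nan)
        for j in range(raw.shape[1]):
            obs_idx = np.flatnonzero(np.isfinite(raw[:, j]))
            if obs_idx.size == 0:
                continue
            permuted[obs_idx, j] = rng.permutation(raw[obs_idx, j])
        null_smoothed = smooth_matrix(permuted, chroms, spec)
        null_calls[p] = _call_counts(null_smoothed, grid, min_samples)

    mean_null = null_calls.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed_calls > 0, mean_null / observed_calls, np.inf)
    passing = np.flatnonzero(fdr <= target_fdr)
    if observed_calls.max() == 0 or passing.size == 0:
        warnings.warn("no threshold achieves the target FDR; returning None")
        threshold = None
    else:
        threshold = float(grid[passing[0]])
    return AeThresholdCalibration(
        threshold=threshold,
        grid=grid,
        observed_calls=observed_calls,
        mean_null_calls=mean_null,
        fdr=fdr,
        n_permutations=n_permutations,
        seed=seed,
    )


def call_aesnps(
    track: AlleleRatioTrack, threshold: float, min_samples: int = 2
) -> pd.DataFrame:
    """Per-SNP allelic-expression calls on the smoothed track.

    A SNP is called when |smoothed| > threshold in >= min_samples samples;
    its sign is the sign of the majority of super-threshold samples (sum of
    super-threshold scores breaks a tie).
    """
    if track.smoothed_ratio is None:
        raise ValidationError("smooth the track before calling aeSNPs")
    mags = np.abs(track.smoothed_ratio)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        super_mask = mags > threshold
        super_mask &= np.isfinite(track.smoothed_ratio)
    n_super = super_mask.sum(axis=1)
    called = n_super >= min_samples
    scores = np.where(super_mask, track.smoothed_ratio, 0.0)
    n_pos = np.sum(scores > 0, axis=1)
    n_neg = np.sum(scores < 0, axis=1)
    sign = np.where(
        n_pos > n_neg, 1, np.where(n_neg > n_pos, -1, np.sign(scores.sum(axis=1)))
    ).astype(int)
    sign[sign == 0] = 1  # degenerate exact tie
    return pd.DataFrame(
        {
            "snp_id": track.snp_ids,
            "chrom": [s.chrom for s in track.loci],
            "position": track.positions,
            "called": called,
            "sign": np.where(called, sign, 0),
            "n_super_threshold": n_super,
        }
    )


def build_aeregions(calls: pd.DataFrame, track: AlleleRatioTrack) -> list[AeRegion]:
    """Aggregate maximal runs of >= 2 consecutive same-sign aeSNPs.

    An uncalled SNP or a sign change breaks a run. The per-sample region
    score is the mean of that sample's smoothed values over member SNPs
    (missing when the sample observes no member).
    """
    if track.smoothed_ratio is None:
        raise ValidationError("smooth the track before building aeRegions")
    regions: list[AeRegion] = []
    called = calls["called"].to_numpy()
    signs = calls["sign"].to_numpy()
    chroms = calls["chrom"].to_numpy()
    run_start = None
    for i in range(len(calls) + 1):
        extend = (
            i < len(calls)
            and called[i]
            and run_start is not None
            and signs[i] == signs[run_start]
            and chroms[i] == chroms[run_start]
        )
        if extend:
            continue
        if run_start is not None and i - run_start >= 2:
            members = np.arange(run_start, i)
            scores = track.smoothed_ratio[members]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sample_scores = np.nanmean(scores, axis=0)
            positions = track.positions[members]
            regions.append(
                AeRegion(
                    region_id=f"aer_{len(regions) + 1}",
                    chrom=str(chroms[run_start]),
                    start=int(positions.min()),
                    end=int(positions.max()) + 1,
                    member_snp_ids=[track.snp_ids[m] for m in members],
                    sign=int(signs[run_start]),
                    sample_scores=sample_scores,
                )
            )
        run_start = i if i < len(calls) and called[i] else None
    return regions


@dataclass
class AeCallResult:
    calibration: AeThresholdCalibration
    calls: pd.DataFrame
    regions: list[AeRegion] = field(default_factory=list)


def run_ae_pipeline(
    track: AlleleRatioTrack,
    target_fdr: float = 0.05,
    min_samples: int = 2,
    n_permutations: int = 10,
    seed: int | None = None,
    spec: HmmSpec | None = None,
) -> AeCallResult:
    """Smooth, calibrate, call and segment in one pass."""
    if spec is None:
        spec = HmmSpec()
    smooth_allelic_ratios(track, spec)
    calibration = calibrate_ae_threshold(
        track, target_fdr, min_samples, n_permutations, seed, spec
    )
    if calibration.threshold is None:
        empty = call_aesnps(track, np.inf, min_samples)
        return AeCallResult(calibration, empty, [])
    calls = call_aesnps(track, calibration.threshold, min_samples)
    regions = build_aeregions(calls, track)
    return AeCallResult(calibration, calls, regions)
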