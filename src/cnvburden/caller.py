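"""Exon-resolution CNV discovery from a read-depth matrix.

The approach follows the classic exome read-depth recipe: per-target
mean-centering, PCA removal of dominant systematic components (batch,
capture and GC structure present as low-rank variation), per-target
z-scoring, then a three-state hidden Markov model (deletion / diploid /
duplication) segmented per sample with the Viterbi algorithm.  Call
confidence is a phred-scaled "some quality": the posterior probability,
from the forward-backward recursions, that the call span harbours at least
one non-diploid target.

States are ordered DEL=0, DIPLOID=1, DUP=2 throughout.  Emissions are
Gaussian with unit variance and means (-M, 0, +M).  Transitions out of
diploid enter either CNV state with probability ``p``; within a CNV the
continuation probability is ``(1 - 1/T)`` attenuated by ``exp(-d/D)`` where
``d`` is the distance between consecutive target midpoints, so distant
targets are less likely to share one event.  Chromosomes are independent
chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .intervals import CnvType, GenomicInterval
from .io import CnvCall, DepthMatrix

__all__ = [
    "NormalizationParams",
    "HmmParams",
    "ZMatrix",
    "normalize_depth",
    "viterbi_segment",
    "call_quality",
    "posterior_matrix",
    "call_cohort",
]

DEL, DIP, DUP = 0, 1, 2
# tie-break preference when Viterbi scores are exactly equal: diploid first,
# so calls are made only on strict evidence
_STATE_PREFERENCE = (DIP, DEL, DUP)


@dataclass(frozen=True)
class NormalizationParams:
    """PCA denoising rule.

    Components whose variance exceeds ``relative_variance_threshold`` times
    the mean component variance are removed (the conventional 0.7-rule);
    ``max_components_removed`` optionally caps how many.
    """

    relative_variance_threshold: float = 0.7
    max_components_removed: int | None = None

    def __post_init__(self) -> None:
        if self.relative_variance_threshold <= 0:
            raise ValueError("relative_variance_threshold must be > 0")


@dataclass(frozen=True)
class HmmParams:
    """Three-state CNV HMM parameters.

    cnv_start_prob
        Probability ``p`` of entering a CNV state from diploid at each step
        (default 1e-8, strongly favouring diploid).
    mean_targets_per_cnv
        Expected CNV extent ``T`` in targets; within-CNV continuation is
        ``1 - 1/T`` (default 6).
    mean_target_distance_bp
        Attenuation scale ``D``; continuation is damped by ``exp(-d/D)``
        for midpoint gap ``d`` (default 70 kb).
    emission_shift
        ``M``, the |z| displacement of the CNV emission means (default 3).
    """

    cnv_start_prob: float = 1e-8
    mean_targets_per_cnv: float = 6.0
    mean_target_distance_bp: float = 70_000.0
    emission_shift: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.cnv_start_prob < 1:
            raise ValueError("cnv_start_prob must be in (0, 1)")
        if self.mean_targets_per_cnv <= 1:
            raise ValueError("mean_targets_per_cnv must be > 1")
        if self.mean_target_distance_bp <= 0 or self.emission_shift <= 0:
            raise ValueError("distance scale and emission shift must be > 0")

    @property
    def initial_log_probs(self) -> np.ndarray:
        p = self.cnv_start_prob
        return np.log(np.array([p, 1.0 - 2.0 * p, p]))

    def transition_log_matrix(self, gap_bp: float) -> np.ndarray:
        """Log transition matrix for one inter-target step of ``gap_bp``."""
        p = self.cnv_start_prob
        f = float(np.exp(-gap_bp / self.mean_target_distance_bp))
        stay = f * (1.0 - 1.0 / self.mean_targets_per_cnv)
        a = np.array(
            [
                [stay, 1.0 - stay - p, p],
                [p, 1.0 - 2.0 * p, p],
                [p, 1.0 - stay - p, stay],
            ]
        )
        return np.log(a)


@dataclass
class ZMatrix:
    """Standardized residual depth: the HMM's emission variable.

    Shape mirrors the depth matrix except that zero-variance targets are
    dropped during normalization (recorded in ``dropped_targets``).
    """

    sample_ids: list[str]
    targets: list[GenomicInterval]
    values: np.ndarray
    n_components_removed: int = 0
    dropped_targets: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


def normalize_depth(
    depth: DepthMatrix, params: NormalizationParams | None = None
) -> ZMatrix:
    """Mean-center, PCA-denoise and z-score a depth matrix.

    Steps: (1) subtract each target's cross-sample mean; (2) remove the
    principal components selected by the relative-variance rule; (3) scale
    every target column to unit variance.  Columns with zero residual
    variance are dropped with a warning.
    """
    params = params or NormalizationParams()
    if depth.n_samples < 2:
        raise ValueError("PCA normalization requires at least 2 samples")
    if depth.n_targets < 2:
        raise ValueError("PCA normalization requires at least 2 targets")
    x = depth.values - depth.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    comp_var = s**2 / (depth.n_samples - 1)
    if comp_var.size and comp_var.mean() > 0:
        remove = np.flatnonzero(
            comp_var > params.relative_variance_threshold * comp_var.mean()
        )
    else:
        remove = np.array([], dtype=int)
    if params.max_components_removed is not None:
        remove = remove[: params.max_components_removed]
    if remove.size:
        x = x - (u[:, remove] * s[remove]) @ vt[remove]
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance targets", stacklevel=2
        )
    kept_targets = [t for t, k in zip(depth.targets, keep) if k]
    dropped = [t for t, k in zip(depth.targets, keep) if not k]
    z = x[:, keep] / sd[keep]
    return ZMatrix(
        list(depth.sample_ids), kept_targets, z, int(remove.size), dropped
    )


@lru_cache(maxsize=8192)
def _trans_cached(hp: HmmParams, gap_bp: float) -> np.ndarray:
    # gaps repeat across samples of a cohort; callers must not mutate this
    return hp.transition_log_matrix(gap_bp)


def _chrom_blocks(
    targets: Sequence[GenomicInterval],
) -> list[tuple[str, int, int]]:
    """Contiguous per-chromosome index ranges; error if unsorted."""
    blocks: list[tuple[str, int, int]] = []
    seen: set[str] = set()
    i = 0
    n = len(targets)
    while i < n:
        chrom = targets[i].chrom
        if chrom in seen:
            raise ValueError(f"targets not grouped by chromosome at {targets[i]}")
        seen.add(chrom)
        j = i
        while j + 1 < n and targets[j + 1].chrom == chrom:
            if targets[j + 1].start < targets[j].start:
                raise ValueError(
                    f"targets not sorted by start at {targets[j + 1]}"
                )
            j += 1
        blocks.append((chrom, i, j + 1))
        i = j + 1
    return blocks


def _midpoint_gaps(targets: Sequence[GenomicInterval]) -> np.ndarray:
    mids = np.array([(t.start + t.end) / 2.0 for t in targets])
    return np.abs(np.diff(mids))


def _emission_loglik(z_block: np.ndarray, hp: HmmParams) -> np.ndarray:
    """(T, 3) Gaussian log-likelihoods for means (-M, 0, +M), unit variance."""
    means = np.array([-hp.emission_shift, 0.0, hp.emission_shift])
    resid = z_block[:, None] - means[None, :]
    return -0.5 * resid**2 - 0.5 * np.log(2.0 * np.pi)


def _viterbi_states(
    z_block: np.ndarray, gaps: np.ndarray, hp: HmmParams
) -> np.ndarray:
    """Most probable state path for one chromosome, ties toward diploid."""
    n = z_block.shape[0]
    loglik = _emission_loglik(z_block, hp)
    pref = np.array(_STATE_PREFERENCE)
    delta = hp.initial_log_probs + loglik[0]
    back = np.empty((n, 3), dtype=np.int8)
    for t in range(1, n):
        loga = _trans_cached(hp, float(gaps[t - 1]))
        scores = delta[:, None] + loga  # (prev, cur)
        best_prev = pref[np.argmax(scores[pref], axis=0)]
        delta = scores[best_prev, np.arange(3)] + loglik[t]
        back[t] = best_prev
    states = np.empty(n, dtype=np.int8)
    states[-1] = pref[int(np.argmax(delta[pref]))]
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def _runs_to_calls(
    states: np.ndarray,
    targets: Sequence[GenomicInterval],
    sample_id: str,
) -> list[CnvCall]:
    calls: list[CnvCall] = []
    i = 0
    n = len(states)
    while i < n:
        if states[i] == DIP:
            i += 1
            continue
        j = i
        while j + 1 < n and states[j + 1] == states[i]:
            j += 1
        cnv_type = CnvType.DEL if states[i] == DEL else CnvType.DUP
        calls.append(
            CnvCall(
                sample_id,
                GenomicInterval(
                    targets[i].chrom, targets[i].start, targets[j].end
                ),
                cnv_type,
                quality=0.0,
                n_targets=j - i + 1,
            )
        )
        i = j + 1
    return calls


def viterbi_segment(
    z_row: np.ndarray,
    targets: Sequence[GenomicInterval],
    hp: HmmParams | None = None,
    sample_id: str = "sample",
) -> list[CnvCall]:
    """Segment one sample's z-scores into CNV calls (quality left at 0).

    Each chromosome is decoded independently; maximal runs of a non-diploid
    state become calls spanning the first to the last run target.
    """
    hp = hp or HmmParams()
    z_row = np.asarray(z_row, dtype=float)
    if z_row.shape[0] != len(targets):
        raise ValueError("z_row length does not match targets")
    calls: list[CnvCall] = []
    for _, i, j in _chrom_blocks(targets):
        block = targets[i:j]
        states = _viterbi_states(z_row[i:j], _midpoint_gaps(block), hp)
        calls.extend(_runs_to_calls(states, block, sample_id))
    return calls


def _forward(
    loglik: np.ndarray, gaps: np.ndarray, hp: HmmParams
) -> np.ndarray:
    n = loglik.shape[0]
    alpha = np.empty((n, 3))
    alpha[0] = hp.initial_log_probs + loglik[0]
    for t in range(1, n):
        loga = _trans_cached(hp, float(gaps[t - 1]))
        alpha[t] = logsumexp(alpha[t - 1][:, None] + loga, axis=0) + loglik[t]
    return alpha


def _backward(
    loglik: np.ndarray, gaps: np.ndarray, hp: HmmParams
) -> np.ndarray:
    n = loglik.shape[0]
    beta = np.zeros((n, 3))
    for t in range(n - 2, -1, -1):
        loga = _trans_cached(hp, float(gaps[t]))
        beta[t] = logsumexp(loga + loglik[t + 1] + beta[t + 1], axis=1)
    return beta


def posterior_matrix(
    z_row: np.ndarray,
    targets: Sequence[GenomicInterval],
    hp: HmmParams | None = None,
) -> np.ndarray:
    """Forward-backward state posteriors, one row per target (rows sum to 1)."""
    hp = hp or HmmParams()
    z_row = np.asarray(z_row, dtype=float)
    out = np.empty((len(targets), 3))
    for _, i, j in _chrom_blocks(targets):
        block = targets[i:j]
        gaps = _midpoint_gaps(block)
        loglik = _emission_loglik(z_row[i:j], hp)
        alpha = _forward(loglik, gaps, hp)
        beta = _backward(loglik, gaps, hp)
        gamma = alpha + beta
        gamma -= logsumexp(gamma, axis=1, keepdims=True)
        out[i:j] = np.exp(gamma)
    return out


def call_quality(
    z_row: np.ndarray,
    targets: Sequence[GenomicInterval],
    call: CnvCall,
    hp: HmmParams | None = None,
) -> float:
    """Phred-scaled probability that the call span is not entirely diploid.

    ``-10 log10 P(all targets in span diploid | data)``, computed exactly by
    a forward pass restricted to the diploid state inside the span, divided
    by the unrestricted evidence.  Capped at 99.
    """
    hp = hp or HmmParams()
    z_row = np.asarray(z_row, dtype=float)
    for chrom, i, j in _chrom_blocks(targets):
        if chrom != call.interval.chrom:
            continue
        block = targets[i:j]
        span = [
            k
            for k, t in enumerate(block)
            if t.start < call.interval.end and t.end > call.interval.start
        ]
        if not span:
            continue
        lo, hi = span[0], span[-1]
        gaps = _midpoint_gaps(block)
        loglik = _emission_loglik(z_row[i:j], hp)
        log_evidence = logsumexp(_forward(loglik, gaps, hp)[-1])
        # restricted pass: only DIPLOID allowed on targets lo..hi
        mask = np.zeros_like(loglik)
        mask[lo : hi + 1, DEL] = -np.inf
        mask[lo : hi + 1, DUP] = -np.inf
        log_restricted = logsumexp(_forward(loglik + mask, gaps, hp)[-1])
        p_all_diploid = np.exp(min(0.0, log_restricted - log_evidence))
        if p_all_diploid <= 1e-99:
            return 99.0
        return float(min(99.0, -10.0 * np.log10(p_all_diploid)))
    raise ValueError(f"call {call.interval} overlaps no target")


def call_cohort(
    depth: DepthMatrix,
    norm_params: NormalizationParams | None = None,
    hmm_params: HmmParams | None = None,
    min_quality: float = 60.0,
) -> list[CnvCall]:
    """Normalize a cohort and call CNVs in every sample.

    Returns the concatenation of per-sample Viterbi calls whose quality is
    at least ``min_quality`` (default 60).
    """
    if depth.n_samples == 0 or depth.n_targets == 0:
        raise ValueError("empty depth matrix")
    hp = hmm_params or HmmParams()
    zm = normalize_depth(depth, norm_params)
    calls: list[CnvCall] = []
    for row, sid in zip(zm.values, zm.sample_ids):
        for call in viterbi_segment(row, zm.targets, hp, sample_id=sid):
            q = call_quality(row, zm.targets, call, hp)
            if q >= min_quality:
                calls.append(
                    CnvCall(
                        call.sample_id,
                        call.interval,
                        call.cnv_type,
                        quality=q,
                        n_targets=call.n_targets,
                    )
                )
    return calls
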