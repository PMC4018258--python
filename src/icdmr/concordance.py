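"""Concordance scoring, mirrored-null thresholding and DMR aggregation.

The concordance of an adjacent probe pair is the mean, across samples, of
the probability that the two probes agree in methylation status:

    c_d = (1/n) * sum_j [ p_d,j * p_{d+1,j} + (1 - p_d,j) * (1 - p_{d+1,j}) ]

It lies in [0, 1], equals 1 exactly when the posteriors are binary and
identical at both probes, and sits near 0.5 for non-differential probes
whose posteriors carry no signal.  The null distribution is estimated
without labels by mirroring the sub-0.5 scores about 0.5 (non-DMR scores
are symmetric about 0.5; DMR scores only inflate the upper tail), and the
calling threshold is the empirical (1 - alpha) quantile of that mirrored
sample.  Runs of at least ``min_scores`` consecutive supra-threshold
pairs within one chromosome form a DMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import chrom_slices
from .mixture import MixtureFit, PosteriorMatrix

__all__ = [
    "ConcordanceTrack",
    "NullModel",
    "DMRegion",
    "DMRSet",
    "concordance_score",
    "concordance_track",
    "estimate_null_threshold",
    "call_dmrs",
    "summarize_dmr",
]

#: fewer sub-0.5 scores than this and the null is declared not estimable
MIN_SUB_HALF = 20
#: mean methylation frequencies inside this closed interval mark regions
#: differentiated in a substantial fraction of samples
HIGH_DIFFERENTIATION_RANGE = (0.15, 0.85)


@dataclass
class ConcordanceTrack:
    """Concordance scores for within-chromosome adjacent probe pairs.

    ``left_index``/``right_index`` index rows of the source matrix; pairs
    never straddle a chromosome boundary, so the track has t - (number of
    chromosomes) entries.
    """

    left_index: np.ndarray
    right_index: np.ndarray
    scores: np.ndarray
    corrected: bool
    matrix_probe_ids: np.ndarray = field(default=None, repr=False)
    matrix_chrom: np.ndarray = field(default=None, repr=False)
    matrix_pos: np.ndarray = field(default=None, repr=False)

    def __len__(self):
        return len(self.scores)


@dataclass
class NullModel:
    """Mirrored empirical null and the resulting calling threshold."""

    alpha: float
    threshold: float
    null_sample_size: int


@dataclass
class DMRegion:
    """One called region (probe indices are 0-based, inclusive)."""

    chrom: str
    start_probe: int
    end_probe: int
    start_pos: int
    end_pos: int
    n_probes: int
    n_scores: int
    mean_concordance: float
    mean_methylation_frequency: float
    per_sample_mean_posterior: np.ndarray
    differentiation_class: str


@dataclass
class DMRSet:
    """Called regions, sorted and non-overlapping, plus sample names."""

    regions: list
    samples: list
    threshold: float

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "chrom": r.chrom,
                "start_pos": r.start_pos,
                "end_pos": r.end_pos,
                "n_probes": r.n_probes,
                "n_scores": r.n_scores,
                "mean_concordance": r.mean_concordance,
                "mean_methylation_frequency": r.mean_methylation_frequency,
                "differentiation_class": r.differentiation_class,
            }
            for r in self.regions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "start_pos",
                "end_pos",
                "n_probes",
                "n_scores",
                "mean_concordance",
                "mean_methylation_frequency",
                "differentiation_class",
            ],
        )


def concordance_score(p_d: np.ndarray, p_d1: np.ndarray) -> float:
    """Agreement score of two posterior vectors, in [0, 1]."""
    a = np.asarray(p_d, dtype=float)
    b = np.asarray(p_d1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("posterior vectors must have equal length")
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    return float(np.mean(a * b + (1.0 - a) * (1.0 - b)))


def concordance_track(posteriors: PosteriorMatrix, corrected: bool = True) -> ConcordanceTrack:
    """Score every within-chromosome adjacent probe pair."""
    P = posteriors.p
    left_parts, right_parts, score_parts = [], [], []
    for sl in chrom_slices(posteriors.chrom):
        if sl.stop - sl.start < 2:
            continue
        idx = np.arange(sl.start, sl.stop - 1)
        a, b = P[sl][:-1], P[sl][1:]
        left_parts.append(idx)
        right_parts.append(idx + 1)
        score_parts.append(np.mean(a * b + (1.0 - a) * (1.0 - b), axis=1))
    empty = np.array([], dtype=int)
    return ConcordanceTrack(
        left_index=np.concatenate(left_parts) if left_parts else empty,
        right_index=np.concatenate(right_parts) if right_parts else empty,
        scores=np.concatenate(score_parts) if score_parts else np.array([]),
        corrected=corrected,
        matrix_probe_ids=posteriors.probe_ids,
        matrix_chrom=posteriors.chrom,
        matrix_pos=getattr(posteriors, "pos", None),
    )


def estimate_null_threshold(
    scores: np.ndarray, alpha: float, min_sub_half: int = MIN_SUB_HALF
) -> NullModel:
    """Mirrored empirical-null threshold at level ``alpha``.

    Scores strictly below 0.5 and their reflections 1 - s form the null
    sample (scores exactly at 0.5 enter neither half); the threshold is
    the empirical (1 - alpha) quantile, linearly interpolated between
    order statistics.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    s = np.asarray(scores, dtype=float)
    sub = s[s < 0.5]
    if sub.size < min_sub_half:
        raise ValueError(
            f"null not estimable: only {sub.size} scores below 0.5 "
            f"(need at least {min_sub_half})"
        )
    null_sample = np.concatenate([sub, 1.0 - sub])
    threshold = float(np.quantile(null_sample, 1.0 - alpha, method="linear"))
    return NullModel(
        alpha=alpha, threshold=threshold, null_sample_size=int(null_sample.size)
    )


def _significant_runs(flags: np.ndarray, min_scores: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_scores, as (start, stop) slices."""
    if flags.size == 0:
        return []
    padded = np.concatenate([[False], flags, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_scores]


def summarize_dmr(
    chrom: str,
    probe_indices: np.ndarray,
    scores: np.ndarray,
    posteriors: PosteriorMatrix,
    pi: np.ndarray,
    pos: np.ndarray,
) -> DMRegion:
    """Fill the summary fields for one run of significant concordances.

    The mean methylation frequency is the average fitted methylated-group
    proportion (pi-hat) over the region's probes; regions with frequency
    inside [0.15, 0.85] are classed as highly differentiated, the rest
    (near-unanimous samples) as low.
    """
    probe_indices = np.asarray(probe_indices, dtype=int)
    freq = float(np.mean(pi[probe_indices]))
    lo, hi = HIGH_DIFFERENTIATION_RANGE
    klass = "high" if lo <= freq <= hi else "low"
    return DMRegion(
        chrom=str(chrom),
        start_probe=int(probe_indices[0]),
        end_probe=int(probe_indices[-1]),
        start_pos=int(pos[probe_indices[0]]),
        end_pos=int(pos[probe_indices[-1]]),
        n_probes=int(probe_indices.size),
        n_scores=int(scores.size),
        mean_concordance=float(np.mean(scores)),
        mean_methylation_frequency=freq,
        per_sample_mean_posterior=posteriors.p[probe_indices].mean(axis=0),
        differentiation_class=klass,
    )


def call_dmrs(
    track: ConcordanceTrack,
    null: NullModel,
    posteriors: PosteriorMatrix,
    fits: list[MixtureFit] | np.ndarray,
    min_scores: int = 3,
    pos: np.ndarray | None = None,
) -> DMRSet:
    """Aggregate runs of significant concordances into DMRs.

    A pair is significant when its score is strictly above the threshold;
    runs of at least ``min_scores`` consecutive significant pairs within a
    chromosome are kept (a run of k scores spans k + 1 probes).
    """
    if min_scores < 1:
        raise ValueError("min_scores must be >= 1")
    pi = (
        np.asarray(fits, dtype=float)
        if isinstance(fits, np.ndarray)
        else np.array([f.pi for f in fits])
    )
    if pos is None:
        pos = track.matrix_pos
    if pos is None:
        pos = np.arange(len(track.matrix_probe_ids))

    flags = track.scores > null.threshold
    # breaks between chromosomes: a run may not cross non-adjacent pairs
    contiguous = np.ones(len(track), dtype=bool)
    if len(track) > 1:
        contiguous[1:] = track.left_index[1:] == track.right_index[:-1]

    regions = []
    start = 0
    for end in list(np.flatnonzero(~contiguous)) + [len(track)]:
        block = slice(start, end)
        for a, b in _significant_runs(flags[block], min_scores):
            sl = slice(start + a, start + b)
            probe_indices = np.arange(track.left_index[sl.start], track.right_index[sl.stop - 1] + 1)
            regions.append(
                summarize_dmr(
                    chrom=track.matrix_chrom[probe_indices[0]],
                    probe_indices=probe_indices,
                    scores=track.scores[sl],
                    posteriors=posteriors,
                    pi=pi,
                    pos=pos,
                )
            )
        start = end
    return DMRSet(regions=regions, samples=list(posteriors.samples), threshold=null.threshold)
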