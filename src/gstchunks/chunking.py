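"""Motor-chunk identification from keypress RT matrices.

A motor chunk is a run of consecutive keypresses executed as one integrated
unit: the chunk-initial press pays the cost of loading the chunk into the
motor buffer and is slow, while within-chunk presses are fast.  Chunks are
identified from a phase's successful trials by comparing each adjacent pair
of keypress positions with a paired two-sided Wilcoxon signed-rank test
across trials, then applying three operating rules:

(i)   a chunk opens on an element whose RT is significantly higher than the
      following keypresses' — position 1 always opens the first segment;
(ii)  an element is appended to the current segment when its RT difference
      from the previous element is non-significant, or significant with a
      *decrease*;
(iii) a significant *increase* in RT marks a chunk boundary: the current
      segment closes and a new one opens.

Segments of length 1 are retained in the partition but are not chunks: a
chunk must contain at least two keypress elements, and singletons are
excluded from both the chunk count and the mean chunk length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import Session

#: Minimum paired samples for a two-sided exact signed-rank test to be able
#: to reach p < 0.05 (2/2^6 = 0.03125 at n = 6).
MIN_TRIALS = 6


@dataclass(frozen=True)
class AdjacentComparison:
    """Wilcoxon comparison of keypress positions n and n+1 across trials."""

    position: int  # n; the pair is (n, n+1)
    p_value: float
    direction: int  # sign of median(RT[n+1] - RT[n]); 0 when undefined
    significant: bool


@dataclass(frozen=True)
class ChunkPartition:
    """Contiguous segmentation of positions 1..N; >=2-element segments are chunks."""

    segments: tuple[tuple[int, int], ...]  # inclusive (start, end) pairs

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("partition needs at least one segment")
        expect = 1
        for start, end in self.segments:
            if start != expect or end < start:
                raise ValueError(f"segments must tile 1..N contiguously, got {self.segments}")
            expect = end + 1

    @classmethod
    def from_lengths(cls, lengths: list[int] | tuple[int, ...]) -> "ChunkPartition":
        segs, start = [], 1
        for ln in lengths:
            segs.append((start, start + ln - 1))
            start += ln
        return cls(tuple(segs))

    @property
    def n_positions(self) -> int:
        return self.segments[-1][1]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.segments)

    @property
    def chunks(self) -> tuple[tuple[int, int], ...]:
        return tuple(s for s in self.segments if s[1] - s[0] + 1 >= 2)

    @property
    def boundaries(self) -> tuple[int, ...]:
        """Chunk-initial positions (segment starts), including position 1."""
        return tuple(start for start, _ in self.segments)

    def is_chunk_initial(self, position: int) -> bool:
        return position in self.boundaries


def chunk_features(partition: ChunkPartition) -> tuple[int, float]:
    """(number of chunks, mean chunk length); singletons excluded from both.

    With no >=2-element segment the count is 0 and the mean is NaN.
    """
    lengths = [e - s + 1 for s, e in partition.chunks]
    if not lengths:
        return 0, math.nan
    return len(lengths), float(np.mean(lengths))


def paired_wilcoxon(diff: np.ndarray) -> tuple[float, float, int]:
    """Two-sided signed-rank test on paired differences.

    Returns ``(W, p, direction)`` where W is the smaller signed-rank sum and
    direction the sign of the median difference.  Zero differences are
    dropped (classical treatment); when every difference is zero the test is
    undefined and ``(0, 1.0, 0)`` is returned.  The exact null distribution
    is used for <= 25 nonzero pairs without ties, a tie-corrected normal
    approximation otherwise.
    """
    diff = np.asarray(diff, dtype=float)
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return 0.0, 1.0, 0
    method = "exact" if nonzero.size <= 25 else "approx"
    if method == "exact" and np.unique(np.abs(nonzero)).size < nonzero.size:
        method = "approx"  # ties: exact distribution invalid, use midranks + normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(nonzero, zero_method="wilcox", method=method)
    direction = int(np.sign(np.median(diff)))
    return float(res.statistic), float(res.pvalue), direction


@dataclass(frozen=True)
class RTMatrix:
    """Successful-trial x keypress-position RT array for one subject phase."""

    values: np.ndarray  # (n_trials, n_positions), ms
    trial_ids: tuple[int, ...]
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (len(self.trial_ids), len(self.positions)):
            raise ValueError("values shape must be (n_trials, n_positions)")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 keypress positions")
        if not np.all(v > 0):
            raise ValueError("all RTs must be positive")
        object.__setattr__(self, "values", v)


def adjacent_wilcoxon(rt: RTMatrix, alpha: float = 0.05) -> list[AdjacentComparison]:
    """Wilcoxon signed-rank tests between successive keypress positions."""
    n_trials, n_pos = rt.values.shape
    if n_trials < MIN_TRIALS:
        raise ValueError(
            f"need >= {MIN_TRIALS} trials for the signed-rank test, got {n_trials}"
        )
    out = []
    for j in range(n_pos - 1):
        diff = rt.values[:, j + 1] - rt.values[:, j]
        _, p, direction = paired_wilcoxon(diff)
        out.append(
            AdjacentComparison(
                position=j + 1, p_value=p, direction=direction,
                significant=bool(p < alpha),
            )
        )
    return out


def segment_chunks(comparisons: list[AdjacentComparison]) -> ChunkPartition:
    """Convert adjacent comparisons into a chunk partition by rules (i)-(iii)."""
    if not comparisons:
        raise ValueError("need at least one adjacent comparison")
    segments, start = [], 1
    for comp in comparisons:
        boundary = comp.significant and comp.direction > 0
        if boundary:
            segments.append((start, comp.position))
            start = comp.position + 1
    segments.append((start, comparisons[-1].position + 1))
    return ChunkPartition(tuple(segments))


def phase_rt_matrix(
    session: Session,
    window: str | tuple[int, int] = "early",
    n_phase_trials: int = 10,
    include_first: bool = True,
) -> RTMatrix:
    """RT matrix over a window of a session's successful trials.

    ``window`` is ``"early"`` (first ``n_phase_trials`` successes), ``"late"``
    (last ``n_phase_trials``), or an inclusive 1-based ``(lo, hi)`` pair of
    successful-trial indices.  ``include_first=False`` drops position 1 (the
    reaction time) from the matrix.
    """
    successes = session.successful_trials
    n = len(successes)
    if window == "early":
        lo, hi = 1, n_phase_trials
    elif window == "late":
        lo, hi = n - n_phase_trials + 1, n
    else:
        lo, hi = window
    if lo < 1 or hi > n:
        raise ValueError(f"window ({lo}, {hi}) outside 1..{n} successful trials")
    selected = successes[lo - 1 : hi]
    if len(selected) < MIN_TRIALS:
        raise ValueError(
            f"window selects {len(selected)} successful trials; "
            f"need >= {MIN_TRIALS}"
        )
    lengths = {len(t.events) for t in selected}
    if len(lengths) != 1:
        raise ValueError("successful trials in a phase must share keypress count")
    values = np.vstack([t.rts() for t in selected])
    positions = tuple(range(1, lengths.pop() + 1))
    if not include_first:
        values = values[:, 1:]
        positions = positions[1:]
    return RTMatrix(values=values, trial_ids=tuple(t.attempt_index for t in selected),
                    positions=positions)


def detect_phase_chunks(
    session: Session,
    window: str | tuple[int, int] = "early",
    alpha: float = 0.05,
    n_phase_trials: int = 10,
    include_first: bool = True,
) -> ChunkPartition:
    """Identify one subject's chunk partition within a practice phase."""
    rt = phase_rt_matrix(session, window, n_phase_trials, include_first)
    return segment_chunks(adjacent_wilcoxon(rt, alpha=alpha))
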