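"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written from first principles — exhaustive
enumeration over key sequences, sign patterns or rank permutations — and
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_path_length(task, max_depth: int = 10) -> int | None:
    """Exhaustive enumeration of all key sequences up to ``max_depth``.

    Returns the length of the first (shortest) sequence that ends on the
    goal after having passed through the sub-goal, or None if no sequence of
    length <= max_depth succeeds.
    """
    keys = sorted(task.key_mapping)
    frontier = [(task.start, task.start == task.subgoal)]
    if task.start == task.goal:  # excluded by task invariants, kept for safety
        return 0
    for depth in range(1, max_depth + 1):
        nxt = []
        for cell, visited in frontier:
            for key in keys:
                dx, dy = task.key_mapping[key]
                target = (cell[0] + dx, cell[1] + dy)
                if not (0 <= target[0] < task.width and 0 <= target[1] < task.height):
                    target = cell
                state = (target, visited or target == task.subgoal)
                if state[0] == task.goal and state[1]:
                    return depth
                nxt.append(state)
        frontier = nxt
    return None


def brute_force_segments(pattern: list[tuple[bool, int]]) -> list[int]:
    """Segment lengths from (significant, direction) pairs, re-derived.

    ``pattern[i]`` describes the comparison between positions i+1 and i+2.
    A new segment starts after every significant increase; everything else
    extends the current one.
    """
    boundaries = [i + 2 for i, (sig, direction) in enumerate(pattern)
                  if sig and direction > 0]
    starts = [1] + boundaries
    ends = [b - 1 for b in boundaries] + [len(pattern) + 1]
    return [e - s + 1 for s, e in zip(starts, ends)]


def brute_force_chunk_features(segment_lengths: list[int]) -> tuple[int, float]:
    chunks = [ln for ln in segment_lengths if ln >= 2]
    if not chunks:
        return 0, math.nan
    return len(chunks), sum(chunks) / len(chunks)


def enum_sign_flip_t_p(diff) -> float:
    """Exact two-sided sign-flip p-value for the paired t statistic."""
    diff = np.asarray(diff, dtype=float)
    n = diff.size

    def t_abs(d):
        m = d.mean()
        sd = math.sqrt(((d - m) ** 2).sum() / (n - 1))
        if sd == 0:
            return math.inf if m != 0 else 0.0
        return abs(m) / (sd / math.sqrt(n))

    obs = t_abs(diff)
    hits = 0
    for signs in itertools.product((1, -1), repeat=n):
        if t_abs(diff * np.array(signs)) >= obs - 1e-12:
            hits += 1
    return hits / 2 ** n


def enum_wilcoxon_p(diff) -> float:
    """Exact two-sided signed-rank p by enumerating all sign patterns.

    Zero differences are dropped; requires tie-free |differences|.
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_plus_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    obs_dev = abs(w_plus_obs - mu)
    hits = 0
    for signs in itertools.product((1, 0), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= obs_dev - 1e-12:
            hits += 1
    return hits / 2 ** n


def _friedman_stat_from_ranks(data: np.ndarray) -> float:
    n, k = data.shape
    ranks = np.vstack([np.argsort(np.argsort(row)) + 1 for row in data]).astype(float)
    col_sums = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * float((col_sums ** 2).sum()) - 3 * n * (k + 1)


def enum_friedman_p(data) -> float:
    """Exact permutation p for the Friedman statistic (tie-free rows only)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    obs = _friedman_stat_from_ranks(data)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for pattern in itertools.product(perms, repeat=n):
        permuted = np.vstack([data[i, list(pattern[i])] for i in range(n)])
        if _friedman_stat_from_ranks(permuted) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def random_task(rng: np.random.Generator):
    """A random small task with a 3-key king-move mapping."""
    from gstchunks import GridTask

    width = int(rng.integers(3, 6))
    height = int(rng.integers(3, 6))
    cells = [(c, r) for c in range(width) for r in range(height)]
    idx = rng.choice(len(cells), size=3, replace=False)
    start, subgoal, goal = (cells[i] for i in idx)
    moves = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    picks = rng.choice(len(moves), size=3, replace=False)
    mapping = {str(k): moves[i] for k, i in zip("456", picks)}
    return GridTask(width=width, height=height, start=start, subgoal=subgoal,
                    goal=goal, key_mapping=mapping)
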