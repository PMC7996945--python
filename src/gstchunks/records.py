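"""Trial-level data containers.

One :class:`Session` holds a single subject's full attempt history in order.
Successful trials reproduce the locked optimal trajectory and carry one
:class:`KeypressEvent` per keypress; error trials (reward below the maximum)
are kept for the learning curve but excluded from all RT analyses.

Keypress response time (RT) at position n is the inter-keypress interval
``timestamp(n) - timestamp(n-1)`` for n >= 2; at position 1 it is the
reaction time, the interval from stimulus onset to the first press.
Execution time is ``timestamp(last) - timestamp(first)``, i.e. the sum of
RTs at positions 2..N — reaction time is excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class KeypressEvent:
    position: int  # 1-based ordinal within the trial
    key: str
    timestamp_ms: float  # from stimulus onset


@dataclass
class TrialRecord:
    """One attempted trial."""

    attempt_index: int  # 1-based over all attempts of the session
    success: bool
    reward: float
    moves: int
    events: list[KeypressEvent]
    after_rest: bool = False

    def __post_init__(self) -> None:
        positions = [e.position for e in self.events]
        if positions != list(range(1, len(self.events) + 1)):
            raise ValueError("keypress positions must run 1..k")
        ts = [e.timestamp_ms for e in self.events]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(e.key for e in self.events)

    def rts(self) -> np.ndarray:
        """Per-position RTs: reaction time at position 1, IKIs after."""
        ts = np.asarray([e.timestamp_ms for e in self.events], dtype=float)
        return np.diff(ts, prepend=0.0)

    def reaction_time(self) -> float:
        if not self.events:
            raise ValueError("trial has no keypresses")
        return self.events[0].timestamp_ms

    def execution_time(self) -> float:
        """Last minus first keypress timestamp; needs >= 2 keypresses."""
        if len(self.events) < 2:
            raise ValueError("execution time undefined for < 2 keypresses")
        return self.events[-1].timestamp_ms - self.events[0].timestamp_ms


@dataclass
class Session:
    """One subject's attempt history plus the locked trajectory's keys."""

    subject_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    locked_keys: tuple[str, ...] | None = None

    @property
    def successful_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.success]

    @property
    def n_successful(self) -> int:
        return sum(t.success for t in self.trials)

    @property
    def n_error(self) -> int:
        return sum(not t.success for t in self.trials)

    def error_counts_per_success(self) -> np.ndarray:
        """Error attempts preceding each successful trial (length n_successful)."""
        counts, run = [], 0
        for t in self.trials:
            if t.success:
                counts.append(run)
                run = 0
            else:
                run += 1
        return np.asarray(counts, dtype=int)


Cohort = list[Session]
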