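"""Synthetic GST behavior with planted chunk structure.

The generator emulates a single-session motor-learning experiment: each
simulated subject explores until the optimal 16-keypress trajectory is
found, locks it, then repeats it until a fixed number of successful trials
is reached, with error attempts interleaved early.

Keypress RTs follow a multiplicative log-normal model around a power law of
practice,

    RT(t, n) = (B + A * t**(-beta)) * m_n * eps,   eps ~ exp(sigma * Z),

where t is the successful-trial index, B the asymptotic keypress time, A the
practice amplitude, beta the practice exponent, and eps unit-median
log-normal noise.  The chunk multiplier ``m_n = 1 + delta`` on chunk-initial
positions plants boundary slowing (position 1 is always chunk-initial);
other positions have ``m_n = 1``.  A fixed extra delay is added at position
1, standing in for stimulus processing and trajectory recall in the reaction
time.  Chunk consolidation is modeled as an abrupt switch from the early
planted partition to the late one at ``consolidation_trial``.

Error attempts follow a decaying per-success failure probability
``q_k = q0 * exp(-r * (k - 1))``: the number of error attempts preceding
success k is geometric with mean ``q_k / (1 - q_k)``, which concentrates
errors in the first trials.  Error attempts carry corrupted, truncated key
sequences and score zero; their RTs are generated but never analyzed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .chunking import ChunkPartition
from .records import KeypressEvent, Session, TrialRecord
from .task import GridTask, SessionState, optimal_trajectory, run_keys, score_trial


def _default_early() -> ChunkPartition:
    return ChunkPartition.from_lengths([3, 4, 5, 4])


def _default_late() -> ChunkPartition:
    return ChunkPartition.from_lengths([7, 5, 4])


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the behavioral simulator (times in ms)."""

    n_subjects: int = 13
    n_successful_trials: int = 60
    planted_partition_early: ChunkPartition = field(default_factory=_default_early)
    planted_partition_late: ChunkPartition = field(default_factory=_default_late)
    consolidation_trial: int = 30  # late partition takes over from this success
    boundary_slowing: float = 0.5  # delta: fractional RT bump on chunk-initial presses
    practice_amplitude: float = 200.0  # A
    practice_exponent: float = 0.5  # beta
    asymptote: float = 200.0  # B
    rt_noise_sigma: float = 0.15  # log-scale SD
    error_rate_initial: float = 0.95  # q0
    error_rate_decay: float = 0.24  # r
    reaction_delay_extra: float = 300.0  # added to position 1 only
    within_chunk_ramp: float = 0.0  # optional within-chunk RT decrease (0..1)
    partition_jitter: bool = False  # per-subject +/-1 boundary shifts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_slowing < 0 or self.practice_exponent < 0:
            raise ValueError("boundary_slowing and practice_exponent must be >= 0")
        if self.asymptote <= 0 or self.rt_noise_sigma < 0:
            raise ValueError("asymptote must be > 0 and sigma >= 0")
        if not 0 <= self.error_rate_initial < 1:
            raise ValueError("error_rate_initial must be in [0, 1)")
        if self.error_rate_decay < 0 or not 0 <= self.within_chunk_ramp < 1:
            raise ValueError("error_rate_decay >= 0 and within_chunk_ramp in [0, 1)")
        ne = self.planted_partition_early.n_positions
        nl = self.planted_partition_late.n_positions
        if ne != nl:
            raise ValueError("planted partitions must cover the same sequence length")
        if len(self.planted_partition_late.segments) > len(self.planted_partition_early.segments):
            raise ValueError("consolidation must not increase the number of segments")


def active_partition(params: GeneratorParams, trial_index: int) -> ChunkPartition:
    """Planted partition in force at successful trial ``trial_index`` (1-based)."""
    if trial_index < params.consolidation_trial:
        return params.planted_partition_early
    return params.planted_partition_late


def sample_rt(
    trial_index: int,
    position: int,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
    partition: ChunkPartition | None = None,
) -> float:
    """Draw one keypress RT (ms) for success ``trial_index``, position ``position``.

    With ``rng=None`` the noise-free value (the distribution's median) is
    returned.
    """
    if trial_index < 1 or not 1 <= position <= params.planted_partition_early.n_positions:
        raise ValueError("trial_index >= 1 and 1 <= position <= N required")
    part = partition if partition is not None else active_partition(params, trial_index)
    base = params.asymptote + params.practice_amplitude * trial_index ** (-params.practice_exponent)
    mult = 1.0
    if part.is_chunk_initial(position):
        mult += params.boundary_slowing
    elif params.within_chunk_ramp > 0:
        seg = next(s for s in part.segments if s[0] <= position <= s[1])
        length = seg[1] - seg[0] + 1
        if length > 1:
            frac = (position - seg[0]) / (length - 1)
            mult *= 1.0 - params.within_chunk_ramp * frac
    rt = base * mult
    if rng is not None and params.rt_noise_sigma > 0:
        rt *= float(np.exp(params.rt_noise_sigma * rng.standard_normal()))
    if position == 1:
        rt += params.reaction_delay_extra
    return rt


def expected_error_fraction(params: GeneratorParams) -> float:
    """Closed-form expected fraction of error attempts in a session."""
    k = np.arange(1, params.n_successful_trials + 1)
    q = params.error_rate_initial * np.exp(-params.error_rate_decay * (k - 1))
    expected_errors = float(np.sum(q / (1 - q)))
    return expected_errors / (params.n_successful_trials + expected_errors)


def _trial_events(
    keys: tuple[str, ...], trial_index: int, params: GeneratorParams,
    rng: np.random.Generator, partition: ChunkPartition,
) -> list[KeypressEvent]:
    ts = 0.0
    events = []
    for pos, key in enumerate(keys, start=1):
        ts += sample_rt(trial_index, pos, params, rng, partition)
        events.append(KeypressEvent(position=pos, key=key, timestamp_ms=ts))
    return events


def _corrupted_keys(
    locked: tuple[str, ...], key_labels: list[str], rng: np.random.Generator
) -> tuple[str, ...]:
    """Replace one key and truncate before the end, guaranteeing failure."""
    n = len(locked)
    pos = int(rng.integers(0, n - 1))  # 0-based corruption position
    alternatives = [k for k in key_labels if k != locked[pos]]
    new_key = alternatives[int(rng.integers(0, len(alternatives)))]
    cut = int(rng.integers(pos + 1, n))  # keep < n keypresses: cannot reach goal
    keys = list(locked[:cut])
    keys[pos] = new_key
    return tuple(keys)


def simulate_session(
    task: GridTask,
    params: GeneratorParams,
    seed: int | np.random.SeedSequence | None = None,
    subject_id: str = "S01",
) -> Session:
    """Simulate one subject's full session.

    The attempt sequence interleaves geometric numbers of error attempts
    with exactly ``n_successful_trials`` successful trials, all of which
    reproduce the locked optimal trajectory.  A successful repetition whose
    sampled duration exceeds the task time limit is demoted to an error
    (timeout) and retried, so success flags always agree with the scoring
    rules.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    locked_traj = optimal_trajectory(task)
    locked = locked_traj.keys
    key_labels = sorted(task.key_mapping)
    jitter = int(rng.integers(-1, 2)) if params.partition_jitter else 0
    part_early = _shift_boundaries(params.planted_partition_early, jitter)
    part_late = _shift_boundaries(params.planted_partition_late, jitter)

    session_state = SessionState()
    trials: list[TrialRecord] = []
    attempt = 0
    after_rest = False
    for k in range(1, params.n_successful_trials + 1):
        part = part_early if k < params.consolidation_trial else part_late
        q_k = params.error_rate_initial * np.exp(-params.error_rate_decay * (k - 1))
        n_errors = int(rng.geometric(1.0 - q_k)) - 1 if q_k > 0 else 0
        for _ in range(n_errors):
            attempt += 1
            keys = _corrupted_keys(locked, key_labels, rng)
            events = _trial_events(keys, k, params, rng, part)
            traj, state = run_keys(task, keys)
            reward = score_trial(task, traj, events[-1].timestamp_ms, session_state.locked)
            trials.append(TrialRecord(
                attempt_index=attempt, success=False, reward=reward,
                moves=state.move_count, events=events, after_rest=after_rest,
            ))
            after_rest = False
        # successful repetition; retry on (rare) sampled timeout
        while True:
            attempt += 1
            events = _trial_events(locked, k, params, rng, part)
            elapsed = events[-1].timestamp_ms
            reward = score_trial(task, locked_traj, elapsed, session_state.locked)
            success = reward == task.max_score
            trials.append(TrialRecord(
                attempt_index=attempt, success=success, reward=reward,
                moves=locked_traj.moves, events=events, after_rest=after_rest,
            ))
            after_rest = False
            if success:
                if session_state.locked is None:
                    session_state.lock(task, locked_traj)
                break
        if k % 20 == 0 and k < params.n_successful_trials:
            after_rest = True  # rest block after every 20 successful trials
    return Session(subject_id=subject_id, trials=trials, locked_keys=locked)


def _shift_boundaries(partition: ChunkPartition, shift: int) -> ChunkPartition:
    """Shift every internal boundary by ``shift`` positions (clipped)."""
    if shift == 0:
        return partition
    n = partition.n_positions
    starts = [s for s, _ in partition.segments[1:]]
    shifted, prev = [], 1
    for s in starts:
        s2 = min(max(s + shift, prev + 1), n)
        shifted.append(s2)
        prev = s2
    segs, start = [], 1
    for s2 in shifted:
        segs.append((start, s2 - 1))
        start = s2
    segs.append((start, n))
    return ChunkPartition(tuple(segs))


def make_cohort(
    task: GridTask,
    params: GeneratorParams,
    n_subjects: int | None = None,
    seed: int | None = None,
) -> list[Session]:
    """Independent sessions with per-subject seeds spawned from the master seed."""
    n = params.n_subjects if n_subjects is None else n_subjects
    if n < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    children = master.spawn(n)
    return [
        simulate_session(task, params, seed=child, subject_id=f"S{i + 1:02d}")
        for i, child in enumerate(children)
    ]


def with_params(params: GeneratorParams, **changes) -> GeneratorParams:
    """A copy of ``params`` with the given fields replaced."""
    return dataclasses.replace(params, **changes)
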