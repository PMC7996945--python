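"""Trial-log and configuration round-tripping.

The trial log is a delimited text table with one row per keypress and a
mandatory header::

    subject_id,attempt_index,success_flag,trial_reward,move_count,
    rest_marker,keypress_position,key_label,timestamp_ms

Within one (subject, attempt) block, keypress positions run 1..k strictly
increasing and timestamps are strictly increasing; the success flag must
agree with the reward (success iff reward equals the maximum score).
Rest-block markers flag the first attempt after a scheduled rest and are
recorded but ignored by all analyses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .chunking import ChunkPartition
from .generate import GeneratorParams
from .records import Cohort, KeypressEvent, Session, TrialRecord
from .task import GridTask

TRIAL_LOG_COLUMNS = [
    "subject_id", "attempt_index", "success_flag", "trial_reward", "move_count",
    "rest_marker", "keypress_position", "key_label", "timestamp_ms",
]


class TrialLogError(ValueError):
    """Malformed trial log; the message names the offending file line(s)."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_trial_log(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for session in cohort:
        for trial in session.trials:
            for ev in trial.events:
                rows.append({
                    "subject_id": session.subject_id,
                    "attempt_index": trial.attempt_index,
                    "success_flag": int(trial.success),
                    "trial_reward": trial.reward,
                    "move_count": trial.moves,
                    "rest_marker": int(trial.after_rest),
                    "keypress_position": ev.position,
                    "key_label": ev.key,
                    "timestamp_ms": ev.timestamp_ms,
                })
    pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_trial_log(path: str | Path, max_score: float = 100.0) -> Cohort:
    """Read and validate a trial log into a cohort of sessions.

    Raises :class:`TrialLogError` naming 1-based file lines (header = line 1)
    on schema mismatch, non-monotone positions/timestamps, or success flags
    inconsistent with rewards.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"subject_id": str, "key_label": str})
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"{path}: missing columns {missing}")
    if df.empty:
        return []
    df["_line"] = df.index + 2  # header occupies line 1
    problems: list[str] = []
    cohort: Cohort = []
    for subject_id, sdf in df.groupby("subject_id", sort=False):
        trials = []
        for attempt, adf in sdf.groupby("attempt_index", sort=True):
            adf = adf.reset_index(drop=True)
            positions = adf["keypress_position"].tolist()
            if positions != list(range(1, len(adf) + 1)):
                problems.append(
                    f"subject {subject_id} attempt {attempt} "
                    f"(lines {adf['_line'].min()}-{adf['_line'].max()}): "
                    f"keypress positions must run 1..k, got {positions}"
                )
                continue
            ts = adf["timestamp_ms"].tolist()
            bad = [int(adf["_line"][i + 1]) for i in range(len(ts) - 1) if ts[i + 1] <= ts[i]]
            if bad:
                problems.append(
                    f"subject {subject_id} attempt {attempt}: non-increasing "
                    f"timestamp at line(s) {bad}"
                )
                continue
            reward = float(adf["trial_reward"].iloc[0])
            success = bool(adf["success_flag"].iloc[0])
            if success != (reward == max_score):
                problems.append(
                    f"subject {subject_id} attempt {attempt} "
                    f"(line {adf['_line'].iloc[0]}): success_flag={int(success)} "
                    f"inconsistent with reward {reward} (max {max_score})"
                )
                continue
            events = [
                KeypressEvent(position=int(r.keypress_position), key=str(r.key_label),
                              timestamp_ms=float(r.timestamp_ms))
                for r in adf.itertuples()
            ]
            trials.append(TrialRecord(
                attempt_index=int(attempt), success=success, reward=reward,
                moves=int(adf["move_count"].iloc[0]), events=events,
                after_rest=bool(adf["rest_marker"].iloc[0]),
            ))
        trials.sort(key=lambda t: t.attempt_index)
        locked = next((t.keys for t in trials if t.success), None)
        cohort.append(Session(subject_id=str(subject_id), trials=trials,
                              locked_keys=locked))
    if problems:
        raise TrialLogError(f"{path}: {len(problems)} malformed trial(s):\n"
                            + "\n".join(problems))
    return cohort


# ---------------------------------------------------------------------------
# task / generator configuration


def task_to_dict(task: GridTask) -> dict:
    return {
        "width": task.width, "height": task.height,
        "start": list(task.start), "subgoal": list(task.subgoal),
        "goal": list(task.goal),
        "key_mapping": {k: list(v) for k, v in task.key_mapping.items()},
        "time_limit_ms": task.time_limit_ms,
        "penalty_per_excess_move": task.penalty_per_excess_move,
        "max_score": task.max_score,
    }


def task_from_dict(d: dict) -> GridTask:
    return GridTask(
        width=int(d["width"]), height=int(d["height"]),
        start=tuple(d["start"]), subgoal=tuple(d["subgoal"]),
        goal=tuple(d["goal"]),
        key_mapping={str(k): tuple(v) for k, v in d["key_mapping"].items()},
        time_limit_ms=float(d["time_limit_ms"]),
        penalty_per_excess_move=float(d["penalty_per_excess_move"]),
        max_score=float(d["max_score"]),
    )


def params_to_dict(params: GeneratorParams) -> dict:
    d = dataclasses.asdict(params)
    d["planted_partition_early"] = list(params.planted_partition_early.lengths)
    d["planted_partition_late"] = list(params.planted_partition_late.lengths)
    return d


def params_from_dict(d: dict) -> GeneratorParams:
    d = dict(d)
    for key in ("planted_partition_early", "planted_partition_late"):
        if key in d and not isinstance(d[key], ChunkPartition):
            d[key] = ChunkPartition.from_lengths(d[key])
    return GeneratorParams(**d)


def save_task_config(task: GridTask, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(task_to_dict(task), sort_keys=False))


def load_task_config(path: str | Path) -> GridTask:
    return task_from_dict(yaml.safe_load(Path(path).read_text()))


def save_params(params: GeneratorParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def load_params(path: str | Path) -> GeneratorParams:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))
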