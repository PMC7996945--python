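"""Grid-sailing task (GST) environment.

The GST is a grid-navigation paradigm: a cursor starts on a fixed cell of a
rectangular grid and must reach a goal cell, but only after passing through a
sub-goal cell, by pressing keys that each map to a fixed displacement
direction.  A minimum-keypress trajectory from start to goal via the sub-goal
is an *optimal path* and earns the maximum score; every excess move costs a
fixed penalty, and running out of time (or, once a trajectory is locked,
deviating from it) scores zero.

Coordinates are 0-based ``(col, row)`` with the origin at the top-left; rows
increase downward, so "up" is ``(0, -1)``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

Cell = tuple[int, int]

#: Default 3-key mapping: numpad keys 4/5/6 -> left / up / right.
DEFAULT_KEY_MAPPING: dict[str, Cell] = {"4": (-1, 0), "5": (0, -1), "6": (1, 0)}


class InfeasiblePathError(ValueError):
    """No key sequence reaches the goal via the sub-goal under this mapping."""


@dataclass(frozen=True)
class GridTask:
    """Immutable task definition: grid, key mapping, waypoints and scoring."""

    width: int = 10
    height: int = 10
    start: Cell = (4, 9)
    subgoal: Cell = (8, 5)
    goal: Cell = (5, 0)
    key_mapping: Mapping[str, Cell] = field(
        default_factory=lambda: dict(DEFAULT_KEY_MAPPING)
    )
    time_limit_ms: float = 9000.0
    penalty_per_excess_move: float = 5.0
    max_score: float = 100.0

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("grid must be at least 2x2")
        for name, cell in (("start", self.start), ("subgoal", self.subgoal),
                           ("goal", self.goal)):
            if not self.in_grid(cell):
                raise ValueError(f"{name} {cell} outside {self.width}x{self.height} grid")
        if len({self.start, self.subgoal, self.goal}) != 3:
            raise ValueError("start, subgoal and goal must be distinct")
        if not self.key_mapping:
            raise ValueError("key mapping must have at least one entry")
        for key, (dx, dy) in self.key_mapping.items():
            if (dx, dy) == (0, 0) or abs(dx) > 1 or abs(dy) > 1:
                raise ValueError(f"key {key!r}: displacement {(dx, dy)} must be a "
                                 "nonzero king move")
        if self.max_score <= 0 or self.penalty_per_excess_move < 0:
            raise ValueError("max_score must be > 0 and penalty >= 0")
        if self.time_limit_ms <= 0:
            raise ValueError("time_limit_ms must be > 0")

    def in_grid(self, cell: Cell) -> bool:
        c, r = cell
        return 0 <= c < self.width and 0 <= r < self.height


@dataclass(frozen=True)
class NavState:
    """Within-trial navigation state: cursor, sub-goal flag, move counter."""

    cursor: Cell
    subgoal_visited: bool = False
    move_count: int = 0


@dataclass(frozen=True)
class Trajectory:
    """A key sequence plus the cells it visits (``len(cells) == len(keys)+1``)."""

    keys: tuple[str, ...]
    cells: tuple[Cell, ...]

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.keys) + 1:
            raise ValueError("cells must have one more entry than keys")

    @property
    def moves(self) -> int:
        return len(self.keys)


def initial_state(task: GridTask) -> NavState:
    return NavState(cursor=task.start, subgoal_visited=False, move_count=0)


def apply_key(task: GridTask, state: NavState, key: str) -> NavState:
    """Apply one keypress.

    An infeasible move (off the grid) leaves the cursor in place but still
    counts as a move.  The sub-goal flag is monotone within a trial.
    """
    if key not in task.key_mapping:
        raise KeyError(f"unknown key label {key!r}")
    dx, dy = task.key_mapping[key]
    target = (state.cursor[0] + dx, state.cursor[1] + dy)
    cursor = target if task.in_grid(target) else state.cursor
    return NavState(
        cursor=cursor,
        subgoal_visited=state.subgoal_visited or cursor == task.subgoal,
        move_count=state.move_count + 1,
    )


def run_keys(task: GridTask, keys: list[str] | tuple[str, ...]) -> tuple[Trajectory, NavState]:
    """Replay a key sequence from the start cell."""
    state = initial_state(task)
    cells = [state.cursor]
    for key in keys:
        state = apply_key(task, state, key)
        cells.append(state.cursor)
    return Trajectory(keys=tuple(keys), cells=tuple(cells)), state


def _product_graph(task: GridTask) -> nx.DiGraph:
    # state = (cell, subgoal_visited); edges follow the key mapping with
    # off-grid moves collapsing onto the same cell.
    g = nx.DiGraph()
    for c in range(task.width):
        for r in range(task.height):
            for visited in (False, True):
                src = ((c, r), visited)
                for dx, dy in task.key_mapping.values():
                    tgt_cell = (c + dx, r + dy)
                    if not task.in_grid(tgt_cell):
                        tgt_cell = (c, r)
                    tgt = (tgt_cell, visited or tgt_cell == task.subgoal)
                    g.add_edge(src, tgt)
    return g


def optimal_path_length(task: GridTask) -> int:
    """Minimum keypresses from start to goal via the sub-goal.

    Shortest path on the product space (cell x sub-goal-visited flag).
    Raises :class:`InfeasiblePathError` when no key sequence works, which can
    happen under restricted 3-direction mappings.
    """
    g = _product_graph(task)
    source = (task.start, task.start == task.subgoal)
    target = (task.goal, True)
    try:
        return nx.shortest_path_length(g, source, target)
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise InfeasiblePathError(
            f"goal {task.goal} unreachable via subgoal {task.subgoal} "
            f"under mapping {dict(task.key_mapping)}"
        ) from exc


def optimal_trajectory(task: GridTask) -> Trajectory:
    """The lexicographically smallest optimal key sequence.

    Among all minimum-length trajectories the one whose key-label sequence
    sorts first is returned, so generators and tests get one deterministic
    path.  BFS expanding keys in sorted order yields exactly that path.
    """
    start = (task.start, task.start == task.subgoal)
    keys_sorted = sorted(task.key_mapping)
    parent: dict[tuple[Cell, bool], tuple[tuple[Cell, bool], str] | None] = {start: None}
    queue: deque[tuple[Cell, bool]] = deque([start])
    goal_state = None
    while queue:
        node = queue.popleft()
        if node[0] == task.goal and node[1]:
            goal_state = node
            break
        cell, visited = node
        for key in keys_sorted:
            dx, dy = task.key_mapping[key]
            tgt_cell = (cell[0] + dx, cell[1] + dy)
            if not task.in_grid(tgt_cell):
                tgt_cell = cell
            nxt = (tgt_cell, visited or tgt_cell == task.subgoal)
            if nxt not in parent:
                parent[nxt] = (node, key)
                queue.append(nxt)
    if goal_state is None:
        raise InfeasiblePathError(
            f"goal {task.goal} unreachable via subgoal {task.subgoal} "
            f"under mapping {dict(task.key_mapping)}"
        )
    keys: list[str] = []
    node = goal_state
    while parent[node] is not None:
        node, key = parent[node]  # type: ignore[misc]
        keys.append(key)
    keys.reverse()
    traj, _ = run_keys(task, keys)
    return traj


def score_trial(
    task: GridTask,
    traj: Trajectory,
    elapsed_ms: float,
    locked: Trajectory | None = None,
) -> float:
    """Score one attempted trial.

    0 on timeout, on not ending at the goal with the sub-goal visited, or on
    any deviation from a locked trajectory; otherwise ``max_score`` minus the
    per-move penalty for each keypress beyond the optimum, floored at 0.
    """
    if traj.cells[0] != task.start:
        raise ValueError("trajectory does not begin at the start cell")
    if elapsed_ms > task.time_limit_ms:
        return 0.0
    replayed, state = run_keys(task, traj.keys)
    if replayed.cells != traj.cells:
        raise ValueError("trajectory cells inconsistent with its key sequence")
    if state.cursor != task.goal or not state.subgoal_visited:
        return 0.0
    if locked is not None and traj.keys != locked.keys:
        return 0.0
    excess = traj.moves - optimal_path_length(task)
    return max(0.0, task.max_score - task.penalty_per_excess_move * excess)


@dataclass
class SessionState:
    """Mutable session-level state: the locked trajectory, if any.

    The first optimal (maximum-score, minimum-length) trajectory a subject
    produces is locked; afterwards only exact reproductions are successful.
    """

    locked: Trajectory | None = None

    def lock(self, task: GridTask, traj: Trajectory) -> "SessionState":
        if traj.moves != optimal_path_length(task):
            raise ValueError("only a minimum-length trajectory can be locked")
        if score_trial(task, traj, elapsed_ms=0.0) != task.max_score:
            raise ValueError("only a maximum-score trajectory can be locked")
        if self.locked is not None and self.locked.keys != traj.keys:
            raise ValueError("a different trajectory is already locked")
        self.locked = traj
        return self


def lock_trajectory(session_state: SessionState, task: GridTask, traj: Trajectory) -> SessionState:
    """Lock ``traj`` as the session's required path (idempotent)."""
    return session_state.lock(task, traj)
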