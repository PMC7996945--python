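"""Navigate the grid-sailing task and score trajectories.

Builds the default 10x10 task (start bottom-center, goal at the top, via a
sub-goal), computes the optimal path and shows how scoring penalizes excess
moves and timeouts.
"""

from gstchunks import GridTask, optimal_path_length, optimal_trajectory, run_keys, score_trial

task = GridTask()
print(f"grid {task.width}x{task.height}, start {task.start}, "
      f"subgoal {task.subgoal}, goal {task.goal}")

n_opt = optimal_path_length(task)
traj = optimal_trajectory(task)
print(f"optimal path: {n_opt} keypresses -> {''.join(traj.keys)}")
print(f"  (key 4 = left, 5 = up, 6 = right)")

print(f"optimal path score: {score_trial(task, traj, elapsed_ms=5000)}")

wiggle, _ = run_keys(task, list(traj.keys[:8]) + ["4", "6"] + list(traj.keys[8:]))
print(f"2 excess moves:     {score_trial(task, wiggle, elapsed_ms=5000)}  "
      "(each excess move costs 5 points)")
print(f"timeout:            {score_trial(task, traj, elapsed_ms=9500)}  "
      "(the 9 s limit was exceeded)")
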