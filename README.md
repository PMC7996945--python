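# gstchunks

Motor-chunk analysis for grid-sailing-task (GST) keypress response times.

When people practice a fixed sequence of keypresses, they do not speed up
uniformly: consecutive presses consolidate into **motor chunks** — runs
executed as one integrated unit, with a slow chunk-initial press (the cost
of loading the chunk into the motor buffer) followed by fast within-chunk
presses. `gstchunks` studies this in an *internally guided* sequencing
paradigm: the GST, where a cursor is steered across a 10×10 grid from a
start cell to a goal cell via a sub-goal, using three keys mapped to fixed
movement directions. Once a subject first produces a minimum-length
("optimal") trajectory, that trajectory is locked and every subsequent
successful trial must reproduce it exactly — so the analyzed keypress
sequence is identical across trials, and only its *timing* evolves.

The package provides, as a plain Python library:

- **Task environment** (`gstchunks.task`) — grid navigation with a
  sub-goal constraint, shortest paths on the (cell × sub-goal-visited)
  product space, reward scoring (100 points maximum, −5 per excess move,
  0 on timeout or deviation from the locked path), trajectory locking.
- **Behavioral simulator** (`gstchunks.generate`) — sessions of 60
  successful trials with interleaved error attempts (~30% of attempts,
  concentrated early), keypress RTs from a log-normal model around a power
  law of practice with planted chunk-boundary slowing, and an abrupt
  early→late chunk consolidation.
- **Chunk detection** (`gstchunks.chunking`) — the core algorithm. For a
  practice phase (10 successful trials), each adjacent pair of keypress
  positions (n, n+1) is compared across trials with a two-sided Wilcoxon
  signed-rank test. Writing RTₙ for the keypress RT at position n, the
  segmentation rules are: a significant *increase* (RTₙ₊₁ > RTₙ, p < α)
  starts a new chunk at n+1; a non-significant difference or a significant
  *decrease* appends n+1 to the current chunk; a segment needs ≥ 2
  keypresses to count as a chunk.
- **Phase statistics** (`gstchunks.stats`) — error-rate and execution-time
  learning curves, Friedman test of trial on execution time, paired t-test
  on early- vs late-phase mean keypress RT, and Wilcoxon signed-rank tests
  on the early→late change in chunk count and mean chunk length. Each test
  reports an exact enumeration/permutation p-value alongside the
  asymptotic one.
- **IO + CLI** (`gstchunks.io`, `gstchunks.cli`) — a one-row-per-keypress
  trial-log format (CSV/TSV) with strict validation, YAML task/parameter
  configs, and a thin `gstchunks generate|detect|report|validate` command
  chain.

## Worked example

```bash
python examples/03_detect_chunks.py
```

```
early phase: segments 1-3 | 4-7 | 8-12 | 13-16
        4 chunks, mean length 4.00 keypresses
late  phase: segments 1-7 | 8-12 | 13-16
        3 chunks, mean length 5.33 keypresses
```

One simulated subject's 16-keypress sequence splits into four chunks in the
early phase (first 10 successful trials); by the late phase (last 10) the
first two chunks have merged — fewer, longer chunks, the signature of chunk
consolidation. At the cohort level (`examples/04_phase_statistics.py`, 13
subjects):

```
mean keypress RT: early 359 ms -> late 270 ms
  paired t(12) = 42.22, p = 2.03e-14 (sign-flip p = 0.000244)
chunks per subject: early 4.00 -> late 3.08
  Wilcoxon W = 0.0, exact p = 0.000532
mean chunk length:  early 3.98 -> late 5.18
  Wilcoxon W = 0.0, exact p = 0.00106
```

Keypresses get ~90 ms faster with practice, the number of chunks drops and
their mean length grows — both changes significant across subjects.

The other examples cover the task environment and scoring
(`examples/01_task_environment.py`) and the learning curves
(`examples/02_simulate_cohort.py`).

## Notes

Algorithmic and modeling choices — the RT model, the error process, the
operationalization of the segmentation rules, default α and phase windows —
are documented in `docs/methods.md`.
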