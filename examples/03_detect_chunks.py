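"""Identify one subject's motor chunks in early and late practice.

Adjacent keypress positions are compared across a phase's 10 successful
trials with Wilcoxon signed-rank tests; a significant RT increase opens a
new chunk.  With practice, small chunks merge into fewer, longer ones.
"""

from gstchunks import (GeneratorParams, GridTask, chunk_features,
                       detect_phase_chunks, simulate_session)

session = simulate_session(GridTask(), GeneratorParams(), seed=1)

for phase in ("early", "late"):
    part = detect_phase_chunks(session, phase, alpha=0.05)
    n, mean_len = chunk_features(part)
    segs = " | ".join(f"{s}-{e}" for s, e in part.segments)
    print(f"{phase:5s} phase: segments {segs}")
    print(f"        {n} chunks, mean length {mean_len:.2f} keypresses")

print("\nA segment needs >= 2 keypresses to count as a chunk; fewer, longer")
print("chunks in the late phase indicate consolidation with practice.")
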