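"""Simulate a 13-subject session cohort and look at the learning curve.

Each subject explores until the 16-keypress optimal trajectory is locked,
then repeats it for 60 successful trials; error attempts concentrate early
and execution time falls with practice (law of practice).
"""

from gstchunks import (GeneratorParams, GridTask, error_rate_curve,
                       expected_error_fraction, friedman_execution, make_cohort)

task = GridTask()
params = GeneratorParams()
cohort = make_cohort(task, params, seed=1)

attempts = sum(len(s.trials) for s in cohort)
errors = sum(s.n_error for s in cohort)
print(f"{len(cohort)} subjects, {attempts} attempts, "
      f"{errors} error trials ({100 * errors / attempts:.1f}%)")
print(f"  (the error process is calibrated for ~"
      f"{100 * expected_error_fraction(params):.1f}% errors in expectation)")

curve = error_rate_curve(cohort)
print(f"mean execution time: trial 1 = {curve.mean_execution_ms[0]:.0f} ms, "
      f"trial 60 = {curve.mean_execution_ms[-1]:.0f} ms")
print(f"mean errors before success: first 5 trials = "
      f"{curve.mean_error_rate[:5].mean():.2f}, last 5 = "
      f"{curve.mean_error_rate[-5:].mean():.2f}")

fr = friedman_execution(cohort)
print(f"Friedman test of trial on execution time: "
      f"chi2({fr.df}) = {fr.chi_square:.1f}, p = {fr.p_value:.3g}")
print("  (a small p says execution time genuinely changes across trials)")
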