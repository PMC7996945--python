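"""Learning-curve and chunk-reorganization statistics.

Covers the session-level analyses that accompany chunk detection: the
error-rate and execution-time learning curves, a Friedman test for the
effect of trial on execution time, a paired t-test on early- vs late-phase
mean keypress RTs, and paired Wilcoxon signed-rank tests on the number and
mean length of chunks across subjects.

Because cohort sizes here are small (~13 subjects), every test reports an
exact (enumeration/permutation) p-value alongside the asymptotic one:
sign-flip enumeration for the paired t and Wilcoxon tests, within-subject
permutation for Friedman.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chunking import chunk_features, detect_phase_chunks, paired_wilcoxon
from .records import Cohort, Session, TrialRecord


def execution_time(trial: TrialRecord) -> float:
    """Last minus first keypress timestamp (ms); reaction time excluded."""
    return trial.execution_time()


# ---------------------------------------------------------------------------
# learning curves


@dataclass(frozen=True)
class LearningCurve:
    """Across-subject curves indexed by successful-trial number (1..K)."""

    mean_execution_ms: np.ndarray
    sem_execution_ms: np.ndarray
    mean_error_rate: np.ndarray  # error attempts preceding each success

    @property
    def n_trials(self) -> int:
        return len(self.mean_execution_ms)


def _success_matrix(cohort: Cohort, fn) -> np.ndarray:
    counts = {s.n_successful for s in cohort}
    if len(counts) != 1:
        raise ValueError(f"subjects have unequal successful-trial counts: {sorted(counts)}")
    return np.vstack([[fn(t) for t in s.successful_trials] for s in cohort])


def error_rate_curve(cohort: Cohort) -> LearningCurve:
    """Mean execution time and mean preceding-error count per success index."""
    et = _success_matrix(cohort, execution_time)
    errors = np.vstack([s.error_counts_per_success() for s in cohort]).astype(float)
    n = et.shape[0]
    sem = et.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(et.shape[1])
    return LearningCurve(
        mean_execution_ms=et.mean(axis=0),
        sem_execution_ms=sem,
        mean_error_rate=errors.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# Friedman test on execution time


@dataclass(frozen=True)
class FriedmanResult:
    chi_square: float
    df: int
    p_value: float  # chi-square approximation
    p_permutation: float | None = None  # within-subject permutation


def _friedman_stat(data: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, _ = stats.friedmanchisquare(*[data[:, j] for j in range(data.shape[1])])
    # fully tied rows make the tie correction degenerate; no effect -> 0
    return 0.0 if math.isnan(stat) else float(stat)


def friedman_permutation_p(
    data: np.ndarray, n_resamples: int = 5000, seed: int | None = 0,
    enumerate_limit: int = 20000,
) -> float:
    """Permutation p-value for the Friedman statistic.

    Permutes measurements within each subject.  Full enumeration when the
    number of within-subject permutation patterns (k!)**n is small, Monte
    Carlo otherwise (with add-one correction).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    observed = _friedman_stat(data)
    n_patterns = math.factorial(k) ** n
    if n_patterns <= enumerate_limit:
        perms = list(itertools.permutations(range(k)))
        count = 0
        for pattern in itertools.product(perms, repeat=n):
            permuted = np.vstack([data[i, list(pattern[i])] for i in range(n)])
            if _friedman_stat(permuted) >= observed - 1e-12:
                count += 1
        return count / n_patterns
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        permuted = np.vstack([row[rng.permutation(k)] for row in data])
        if _friedman_stat(permuted) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)


def friedman_execution(
    cohort: Cohort, permutation: bool = False, n_resamples: int = 5000,
    seed: int | None = 0,
) -> FriedmanResult:
    """Friedman rank test of trial number on execution time (subjects x trials)."""
    et = _success_matrix(cohort, execution_time)
    n, k = et.shape
    if k < 3:
        raise ValueError("Friedman test needs >= 3 trials")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.friedmanchisquare(*[et[:, j] for j in range(k)])
    if math.isnan(stat):  # every subject fully tied across trials
        stat, p = 0.0, 1.0
    p_perm = friedman_permutation_p(et, n_resamples, seed) if permutation else None
    return FriedmanResult(chi_square=float(stat), df=k - 1, p_value=float(p),
                          p_permutation=p_perm)


# ---------------------------------------------------------------------------
# early vs late phase comparisons


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    df: int
    p_value: float  # Student-t reference
    p_sign_flip: float  # exact/MC sign-flip permutation
    mean_early: float
    mean_late: float
    per_subject_early: tuple[float, ...]
    per_subject_late: tuple[float, ...]
    degenerate: bool = False  # zero-variance differences


def sign_flip_p(diff: np.ndarray, n_resamples: int = 100000, seed: int | None = 0,
                enumerate_limit: int = 1 << 18) -> float:
    """Two-sided sign-flip permutation p for the mean of paired differences.

    Uses the t statistic as the flip-invariant ordering; exact enumeration of
    all 2**n sign patterns when feasible, Monte Carlo otherwise.
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.size

    def tstat(d: np.ndarray) -> float:
        sd = d.std(ddof=1)
        if sd == 0:
            return math.inf if d.mean() != 0 else 0.0
        return abs(d.mean()) / (sd / math.sqrt(n))

    observed = tstat(diff)
    if 2 ** n <= enumerate_limit:
        count = 0
        for signs in itertools.product((1.0, -1.0), repeat=n):
            if tstat(diff * np.asarray(signs)) >= observed - 1e-12:
                count += 1
        return count / 2 ** n
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
    flipped = diff * signs
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.abs(means) / (sds / math.sqrt(n))
    ts = np.where(np.isnan(ts), 0.0, ts)
    return (int(np.sum(ts >= observed - 1e-12)) + 1) / (n_resamples + 1)


def mean_phase_rts(
    session: Session, n_phase_trials: int = 10, include_first: bool = True,
) -> tuple[float, float]:
    """A subject's mean keypress RT over all positions in each phase."""
    from .chunking import phase_rt_matrix

    early = phase_rt_matrix(session, "early", n_phase_trials, include_first)
    late = phase_rt_matrix(session, "late", n_phase_trials, include_first)
    return float(early.values.mean()), float(late.values.mean())


def phase_rt_ttest(
    cohort: Cohort, n_phase_trials: int = 10, include_first: bool = True,
) -> PairedTResult:
    """Paired t-test of per-subject mean keypress RT, early vs late phase."""
    if len(cohort) < 2:
        raise ValueError("paired t-test needs >= 2 subjects")
    pairs = [mean_phase_rts(s, n_phase_trials, include_first) for s in cohort]
    early = np.asarray([p[0] for p in pairs])
    late = np.asarray([p[1] for p in pairs])
    diff = early - late
    degenerate = bool(np.ptp(diff) == 0)
    if degenerate:
        # zero-variance differences: t is 0/0 (no change) or infinite
        t = 0.0 if diff[0] == 0 else math.copysign(math.inf, diff[0])
        p = 1.0 if diff[0] == 0 else 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_rel(early, late)
    return PairedTResult(
        statistic=float(t), df=len(cohort) - 1, p_value=float(p),
        p_sign_flip=sign_flip_p(diff),
        mean_early=float(early.mean()), mean_late=float(late.mean()),
        per_subject_early=tuple(early), per_subject_late=tuple(late),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class WilcoxonPhaseResult:
    """Paired signed-rank comparison of one chunk feature, early vs late."""

    feature: str
    statistic: float  # smaller signed-rank sum W
    z: float  # normal-approximation z (0 when undefined)
    p_exact: float
    p_approx: float
    n_pairs: int  # subjects entering the test
    mean_early: float
    mean_late: float


def _wilcoxon_phase(feature: str, early: np.ndarray, late: np.ndarray) -> WilcoxonPhaseResult:
    diff = late - early
    w, p_exact, _ = paired_wilcoxon(diff)
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        z, p_approx = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(nonzero, zero_method="wilcox", method="approx")
        z = float(res.zstatistic) if np.isfinite(res.zstatistic) else 0.0
        p_approx = float(res.pvalue)
    return WilcoxonPhaseResult(
        feature=feature, statistic=w, z=z, p_exact=p_exact, p_approx=p_approx,
        n_pairs=len(early), mean_early=float(np.mean(early)),
        mean_late=float(np.mean(late)),
    )


@dataclass(frozen=True)
class ReorganizationResult:
    n_chunks: WilcoxonPhaseResult
    chunk_length: WilcoxonPhaseResult
    per_subject: tuple[dict, ...]  # subject_id, phase features
    excluded_from_length: tuple[str, ...]  # subjects lacking chunks in a phase


def chunk_reorganization_test(
    cohort: Cohort, alpha: float = 0.05, n_phase_trials: int = 10,
    include_first: bool = True,
) -> ReorganizationResult:
    """Wilcoxon tests of early-to-late change in chunk count and mean length.

    Subjects with no detected chunk in a phase enter the count test with 0
    chunks but are excluded pairwise from the length test.
    """
    rows, excluded = [], []
    for s in cohort:
        feats = {}
        for phase in ("early", "late"):
            part = detect_phase_chunks(s, phase, alpha, n_phase_trials, include_first)
            n_chunks, mean_len = chunk_features(part)
            feats[phase] = (n_chunks, mean_len)
        rows.append({
            "subject_id": s.subject_id,
            "n_chunks_early": feats["early"][0], "n_chunks_late": feats["late"][0],
            "length_early": feats["early"][1], "length_late": feats["late"][1],
        })
        if math.isnan(feats["early"][1]) or math.isnan(feats["late"][1]):
            excluded.append(s.subject_id)
    counts_early = np.asarray([r["n_chunks_early"] for r in rows], dtype=float)
    counts_late = np.asarray([r["n_chunks_late"] for r in rows], dtype=float)
    keep = [i for i, r in enumerate(rows) if r["subject_id"] not in excluded]
    len_early = np.asarray([rows[i]["length_early"] for i in keep], dtype=float)
    len_late = np.asarray([rows[i]["length_late"] for i in keep], dtype=float)
    if len(keep) == 0:
        raise ValueError("no subject has chunks in both phases")
    return ReorganizationResult(
        n_chunks=_wilcoxon_phase("n_chunks", counts_early, counts_late),
        chunk_length=_wilcoxon_phase("mean_chunk_length", len_early, len_late),
        per_subject=tuple(rows),
        excluded_from_length=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# combined report


@dataclass(frozen=True)
class PhaseComparisonReport:
    learning: LearningCurve
    friedman: FriedmanResult
    rt_ttest: PairedTResult
    reorganization: ReorganizationResult
    alpha: float

    def to_dict(self) -> dict:
        lc = self.learning
        return {
            "alpha": self.alpha,
            "learning_curve": {
                "mean_execution_ms": lc.mean_execution_ms.tolist(),
                "sem_execution_ms": lc.sem_execution_ms.tolist(),
                "mean_error_rate": lc.mean_error_rate.tolist(),
            },
            "friedman": {
                "chi_square": self.friedman.chi_square, "df": self.friedman.df,
                "p_value": self.friedman.p_value,
                "p_permutation": self.friedman.p_permutation,
            },
            "phase_rt_ttest": {
                "t": self.rt_ttest.statistic, "df": self.rt_ttest.df,
                "p_value": self.rt_ttest.p_value,
                "p_sign_flip": self.rt_ttest.p_sign_flip,
                "mean_early_ms": self.rt_ttest.mean_early,
                "mean_late_ms": self.rt_ttest.mean_late,
                "degenerate": self.rt_ttest.degenerate,
            },
            "reorganization": {
                "per_subject": list(self.reorganization.per_subject),
                "excluded_from_length": list(self.reorganization.excluded_from_length),
                "n_chunks": vars(self.reorganization.n_chunks).copy(),
                "chunk_length": vars(self.reorganization.chunk_length).copy(),
            },
        }


def build_report(
    cohort: Cohort, alpha: float = 0.05, n_phase_trials: int = 10,
    include_first: bool = True,
) -> PhaseComparisonReport:
    """Run the full analysis battery on a cohort."""
    return PhaseComparisonReport(
        learning=error_rate_curve(cohort),
        friedman=friedman_execution(cohort),
        rt_ttest=phase_rt_ttest(cohort, n_phase_trials, include_first),
        reorganization=chunk_reorganization_test(cohort, alpha, n_phase_trials, include_first),
        alpha=alpha,
    )
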