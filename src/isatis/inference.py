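"""Between-arm comparisons for two-arm survey data.

Participation is compared with an exact Fisher test on the 2x2
responder table; completion delays with the Wilcoxon-Mann-Whitney
rank-sum test; satisfaction scores and Cronbach alpha coefficients with
Monte-Carlo permutation tests that shuffle whole patients between arms;
and standardized mean differences are reported as Cohen d with pooled SD
and patient-level bootstrap CIs.

The Fisher test is implemented directly by hypergeometric enumeration
with log-factorial accumulation; the two-sided p sums the probabilities
of all tables with the observed margins whose point probability does not
exceed that of the observed table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .questionnaire import QuestionnaireSpec
from .reliability import (
    GLOBAL_SCALE,
    bootstrap_ci,
    cronbach_alpha,
    item_matrix,
)
from .scoring import ARMS, PatientRecord, ScoreSet, classify_responder

__all__ = [
    "ContingencyTable2x2",
    "PermutationResult",
    "EffectSize",
    "fisher_exact_2x2",
    "mann_whitney",
    "permutation_diff_test",
    "cohen_d",
    "compare_arms",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = arm and columns = responder / nonresponder."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_value: float
    n_perm: int
    seed: int | None
    statistic_name: str


@dataclass(frozen=True)
class EffectSize:
    """Cohen d (first group minus second, pooled SD) with bootstrap CI."""

    d: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


def _log_table_prob(a: int, r1: int, r2: int, c1: int) -> float:
    """log hypergeometric probability of a table with cell a and fixed margins."""
    n = r1 + r2
    return (
        math.lgamma(r1 + 1)
        - math.lgamma(a + 1)
        - math.lgamma(r1 - a + 1)
        + math.lgamma(r2 + 1)
        - math.lgamma(c1 - a + 1)
        - math.lgamma(r2 - (c1 - a) + 1)
        - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
    )


def fisher_exact_2x2(t: ContingencyTable2x2, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those whose point probability is at
    most that of the observed table (within ``rel_tol`` relative tolerance
    for ties).
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    if r1 == 0 or r2 == 0 or c1 == 0 or t.b + t.d == 0:
        raise ValueError("a margin of the table is empty")
    lp_obs = _log_table_prob(t.a, r1, r2, c1)
    cutoff = lp_obs + math.log1p(rel_tol)
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    p = 0.0
    for a in range(a_min, a_max + 1):
        lp = _log_table_prob(a, r1, r2, c1)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value with midranks for ties.

    Exact enumeration for small tie-free samples, normal approximation
    with tie correction otherwise.  Two constant identical samples have
    no evidence of a shift and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def _perm_mean_fast(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    na = a.size
    observed = a.mean() - b.mean()
    total = pooled.sum()
    n = pooled.size
    # one shuffled dataset per row; the permuted group-A mean determines
    # the difference because the pooled total is fixed
    count = 0
    chunk = max(1, min(n_perm, 200_000 // max(n, 1)))
    done = 0
    thresh = abs(observed) - 1e-12 * (1 + abs(observed))
    while done < n_perm:
        m = min(chunk, n_perm - done)
        mat = np.tile(pooled, (m, 1))
        mat = rng.permuted(mat, axis=1)
        sa = mat[:, :na].sum(axis=1)
        diffs = sa / na - (total - sa) / (n - na)
        count += int(np.sum(np.abs(diffs) >= thresh))
        done += m
    p = (1 + count) / (n_perm + 1)
    return observed, p


def permutation_diff_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    stat: Callable[[np.ndarray], float] | str = "mean",
    n_perm: int = 10_000,
    seed: int | None = None,
    max_retries: int = 100,
) -> PermutationResult:
    """Monte-Carlo permutation test of ``stat(A) - stat(B)``.

    Patient rows are pooled and reassigned to the two groups (preserving
    group sizes) ``n_perm`` times; the two-sided p-value uses the add-one
    estimator ``(1 + #{|diff*| >= |observed|}) / (n_perm + 1)``.  With a
    2-D table the whole row (a patient's item vector) moves between
    groups, so statistics such as Cronbach alpha permute coherently.

    ``stat`` may be the string ``"mean"`` (vectorized fast path on 1-D
    data) or any callable mapping a rows-array to a scalar.  A shuffle on
    which the statistic is undefined is redrawn, up to ``max_retries``
    consecutive times.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    if stat == "mean" and a.ndim == 1:
        observed, p = _perm_mean_fast(a, b, n_perm, rng)
        return PermutationResult(float(observed), float(p), n_perm, seed, "mean")

    fn: Callable[[np.ndarray], float] = np.mean if stat == "mean" else stat  # type: ignore[assignment]
    name = "mean" if stat == "mean" else getattr(stat, "__name__", "stat")
    observed = float(fn(a) - fn(b))
    pooled = np.concatenate([a, b], axis=0)
    na, n = a.shape[0], a.shape[0] + b.shape[0]
    thresh = abs(observed) - 1e-12 * (1 + abs(observed))
    count = 0
    for _ in range(n_perm):
        for attempt in range(max_retries + 1):
            idx = rng.permutation(n)
            try:
                diff = fn(pooled[idx[:na]]) - fn(pooled[idx[na:]])
                break
            except (ValueError, ZeroDivisionError, FloatingPointError):
                continue
        else:
            raise RuntimeError(
                f"statistic undefined on {max_retries} consecutive shuffles"
            )
        if abs(diff) >= thresh:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(observed, float(p), n_perm, seed, name)


def cohen_d(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 0,
    seed: int | None = None,
) -> EffectSize:
    """Standardized mean difference (x minus y) with pooled SD.

    ``d = (mean(x) - mean(y)) / s_pooled`` with
    ``s_pooled^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)``.  When
    ``n_boot > 0`` a percentile-bootstrap CI resampling patients within
    each group is attached; otherwise the CI is NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")

    def _d(xs: np.ndarray, ys: np.ndarray) -> float:
        s2 = ((xs.size - 1) * xs.var(ddof=1) + (ys.size - 1) * ys.var(ddof=1)) / (
            xs.size + ys.size - 2
        )
        if not s2 > 0:
            raise ValueError("zero pooled standard deviation")
        return float((xs.mean() - ys.mean()) / math.sqrt(s2))

    d = _d(x, y)
    lo = hi = math.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            for _ in range(100):
                xs = x[rng.integers(0, n1, n1)]
                ys = y[rng.integers(0, n2, n2)]
                try:
                    reps[b] = _d(xs, ys)
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("degenerate resamples in effect-size bootstrap")
        lo, hi = np.quantile(reps, [0.025, 0.975])
    return EffectSize(d=d, ci_low=float(lo), ci_high=float(hi), n1=n1, n2=n2)


def _scale_values(
    scores: Sequence[ScoreSet], scale: str, arm: str
) -> np.ndarray:
    if scale == GLOBAL_SCALE:
        vals = [s.global_score for s in scores if s.arm == arm]
    else:
        vals = [s.dimension_scores.get(scale) for s in scores if s.arm == arm]
    return np.asarray([v for v in vals if v is not None], dtype=float)


def compare_arms(
    records: Sequence[PatientRecord],
    scores: Sequence[ScoreSet],
    spec: QuestionnaireSpec,
    *,
    n_boot: int = 2000,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha_comparison: bool = True,
    alpha_n_perm: int | None = None,
) -> dict:
    """Full between-arm comparison report.

    For each dimension and the global scale: per-arm mean with bootstrap
    CI and n, mean difference (internet minus telephone) with bootstrap
    CI, permutation p, and Cohen d with CI.  Also: Fisher exact p on
    participation and Mann-Whitney p on completion delays, and (when
    ``alpha_comparison``) permutation p-values for the between-arm
    difference in Cronbach alpha per scale.
    """
    present = {s.arm for s in scores}
    if set(ARMS) - present:
        raise ValueError(f"both arms required, missing {sorted(set(ARMS) - present)}")
    root = np.random.SeedSequence(seed)
    scales = list(spec.dimension_names) + [GLOBAL_SCALE]

    responder_flags = {s.patient_id: s.responder for s in scores}
    by_arm_records = {arm: [r for r in records if r.arm == arm] for arm in ARMS}

    # participation
    n_resp = {arm: sum(1 for s in scores if s.arm == arm and s.responder) for arm in ARMS}
    n_tot = {arm: sum(1 for s in scores if s.arm == arm) for arm in ARMS}
    table = ContingencyTable2x2(
        a=n_resp["internet"],
        b=n_tot["internet"] - n_resp["internet"],
        c=n_resp["telephone"],
        d=n_tot["telephone"] - n_resp["telephone"],
    )
    participation_p = fisher_exact_2x2(table)

    # completion delays among responders
    delays = {
        arm: [
            r.delay_days
            for r in by_arm_records[arm]
            if r.delay_days is not None and responder_flags.get(r.patient_id, False)
        ]
        for arm in ARMS
    }
    delay_p = (
        mann_whitney(delays["internet"], delays["telephone"])
        if delays["internet"] and delays["telephone"]
        else None
    )

    report: dict = {
        "participation": {
            "table": {"internet": [table.a, table.b], "telephone": [table.c, table.d]},
            "fisher_p": participation_p,
        },
        "delay": {
            "median": {
                arm: float(np.median(delays[arm])) if delays[arm] else None
                for arm in ARMS
            },
            "mann_whitney_p": delay_p,
        },
        "scales": {},
    }

    for scale in scales:
        child = root.spawn(1)[0]
        sub = [int(s.generate_state(1)[0] % 2**31) for s in child.spawn(4)]
        x = _scale_values(scores, scale, "internet")
        y = _scale_values(scores, scale, "telephone")
        entry: dict = {
            "n": {"internet": int(x.size), "telephone": int(y.size)},
        }
        if x.size >= 2 and y.size >= 2:
            ci_x = bootstrap_ci(np.mean, x, n_boot=n_boot, seed=sub[0])
            ci_y = bootstrap_ci(np.mean, y, n_boot=n_boot, seed=sub[1])
            perm = permutation_diff_test(x, y, "mean", n_perm=n_perm, seed=sub[2])
            diff_lo, diff_hi = _bootstrap_diff_ci(x, y, n_boot, sub[1] ^ sub[0])
            try:
                es = cohen_d(x, y, n_boot=n_boot, seed=sub[3])
                effect = {"d": es.d, "ci_low": es.ci_low, "ci_high": es.ci_high}
            except ValueError:
                effect = None
            entry.update(
                {
                    "mean": {"internet": float(x.mean()), "telephone": float(y.mean())},
                    "mean_ci": {"internet": ci_x, "telephone": ci_y},
                    "difference": perm.observed_diff,
                    "difference_ci": [diff_lo, diff_hi],
                    "permutation_p": perm.p_value,
                    "n_perm": perm.n_perm,
                    "effect_size": effect,
                }
            )
        else:
            entry["note"] = "not estimable: fewer than 2 score-defined patients in an arm"
        report["scales"][scale] = entry

    if alpha_comparison:
        report["alpha_comparison"] = _alpha_permutation(
            records, spec, responder_flags, scales,
            alpha_n_perm or n_perm, root.spawn(1)[0],
        )
    return report


def _bootstrap_diff_ci(
    x: np.ndarray, y: np.ndarray, n_boot: int, seed: int
) -> tuple[float, float]:
    """Percentile CI of the mean difference, resampling within each arm."""
    rng = np.random.default_rng(seed)
    bx = x[rng.integers(0, x.size, (n_boot, x.size))].mean(axis=1)
    by = y[rng.integers(0, y.size, (n_boot, y.size))].mean(axis=1)
    lo, hi = np.quantile(bx - by, [0.025, 0.975])
    return float(lo), float(hi)


def _alpha_permutation(
    records: Sequence[PatientRecord],
    spec: QuestionnaireSpec,
    responder_flags: dict[str, bool],
    scales: Sequence[str],
    n_perm: int,
    seed_seq: np.random.SeedSequence,
) -> dict:
    """Permutation p for the between-arm alpha difference per scale.

    Whole patient rows (item vectors) are shuffled between arms so that
    within-patient correlation is preserved.
    """
    out: dict = {}
    for scale, child in zip(scales, seed_seq.spawn(len(scales))):
        sub = int(child.generate_state(1)[0] % 2**31)
        ma = item_matrix(
            [r for r in records if r.arm == "internet"], spec, scale, responder_flags
        )
        mb = item_matrix(
            [r for r in records if r.arm == "telephone"], spec, scale, responder_flags
        )
        try:
            res = permutation_diff_test(
                ma, mb, stat=cronbach_alpha, n_perm=n_perm, seed=sub
            )
            out[scale] = {
                "alpha_diff": res.observed_diff,
                "permutation_p": res.p_value,
                "n_perm": res.n_perm,
            }
        except (ValueError, RuntimeError) as exc:
            out[scale] = {"note": f"not estimable: {exc}"}
    return out
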