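"""Internal-consistency estimation: Cronbach alpha with bootstrap CIs.

Alpha is computed from the item covariance matrix via the generalized
formula ``(k/(k-1)) * (1 - trace(C)/sum(C))``.  Because partially
completed questionnaires still contribute to a scale whenever its score is
defined, the covariance matrix is by default estimated from
pairwise-complete observations over those rows; a listwise option restricts
to fully complete rows for sensitivity analyses.  Confidence intervals are
percentile bootstrap over patients (rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .questionnaire import QuestionnaireSpec
from .scoring import ARMS, PatientRecord, dimension_score, global_score, recode_item

__all__ = [
    "AlphaEstimate",
    "pairwise_covariance",
    "cronbach_alpha",
    "bootstrap_ci",
    "item_matrix",
    "alpha_table",
    "GLOBAL_SCALE",
]

GLOBAL_SCALE = "global"


class DegenerateScaleError(ValueError):
    """Total-score variance is zero: alpha is undefined."""


@dataclass(frozen=True)
class AlphaEstimate:
    """Point estimate with percentile-bootstrap CI for one scale and arm."""

    alpha: float
    ci_low: float
    ci_high: float
    n_patients: int
    k_items: int
    n_boot: int
    seed: int | None


def pairwise_covariance(m: np.ndarray) -> np.ndarray:
    """Covariance matrix from pairwise-complete observations (ddof=1).

    ``m`` is patients x items with NaN for missing cells.  Entry (i, j)
    uses exactly the rows where both items are observed; entries with
    fewer than two such rows are NaN.
    """
    m = np.asarray(m, dtype=float)
    mask = ~np.isnan(m)
    x = np.where(mask, m, 0.0)
    p = mask.astype(float)
    n = p.T @ p  # pairwise counts
    sxy = x.T @ x
    sx = x.T @ p  # sum of item i over rows where j present
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (sxy - sx * sx.T / n) / (n - 1.0)
    cov[n < 2] = np.nan
    return cov


def cronbach_alpha(m: np.ndarray, *, listwise: bool = False) -> float:
    """Cronbach alpha of an items matrix (patients x items, NaN = missing).

    ``alpha = k/(k-1) * (1 - trace(C)/sum(C))`` where C is the item
    covariance matrix, pairwise-complete by default.  The result is <= 1
    and may be negative.

    Raises
    ------
    DegenerateScaleError
        If the implied total-score variance (sum of C) is not positive, or
        some item pair has no overlapping observations.
    ValueError
        If the matrix has fewer than 2 items or fewer than 2 rows.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("item matrix must be 2-D (patients x items)")
    n, k = m.shape
    if k < 2:
        raise ValueError(f"need at least 2 items, got {k}")
    if n < 2:
        raise ValueError(f"need at least 2 patients, got {n}")
    if listwise:
        m = m[~np.isnan(m).any(axis=1)]
        if m.shape[0] < 2:
            raise ValueError("fewer than 2 complete rows under listwise deletion")
    cov = pairwise_covariance(m)
    if np.isnan(cov).any():
        raise DegenerateScaleError(
            "covariance not estimable: an item pair has < 2 joint observations"
        )
    total = cov.sum()
    if not total > 0:
        raise DegenerateScaleError("degenerate scale: zero total-score variance")
    return float(k / (k - 1) * (1.0 - np.trace(cov) / total))


def bootstrap_ci(
    stat: Callable[[np.ndarray], float],
    data: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``stat`` over row resamples.

    Rows (patients) are resampled with replacement; the interval is the
    ``(1-level)/2`` and ``1-(1-level)/2`` empirical quantiles of the
    replicate statistics.  A resample on which the statistic is undefined
    (raises) is redrawn, up to ``max_retries`` consecutive times.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] == 0:
        raise ValueError("empty data")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    reps = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                reps[b] = stat(data[idx])
                break
            except (ValueError, ZeroDivisionError, FloatingPointError):
                n_redrawn += 1
                continue
        else:
            raise RuntimeError(
                f"statistic undefined on {max_retries} consecutive resamples"
            )
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def item_matrix(
    records: Iterable[PatientRecord],
    spec: QuestionnaireSpec,
    scale: str,
    responder_flags: dict[str, bool] | None = None,
) -> np.ndarray:
    """Valued-item matrix for a scale, restricted to score-defined patients.

    ``scale`` is a dimension name or :data:`GLOBAL_SCALE`.  Rows are the
    patients whose corresponding score is defined (responders only when
    ``responder_flags`` is given); columns are the scale's items; cells
    are valued scores in {0, 25, 50, 75, 100} or NaN.
    """
    if scale == GLOBAL_SCALE:
        items = spec.scored_items
        defined = lambda r: global_score(r, spec) is not None  # noqa: E731
    else:
        items = spec.items_of(scale)
        defined = lambda r: dimension_score(r, scale, spec) is not None  # noqa: E731
    rows = []
    for rec in records:
        if responder_flags is not None and not responder_flags.get(
            rec.patient_id, False
        ):
            continue
        if not defined(rec):
            continue
        row = [
            np.nan if (c := rec.responses.get(item)) is None else _value_or_nan(c)
            for item in items
        ]
        rows.append(row)
    return np.asarray(rows, dtype=float).reshape(len(rows), len(items))


def _value_or_nan(code: int) -> float:
    v = recode_item(code)
    return np.nan if v is None else v


def alpha_table(
    records: Sequence[PatientRecord],
    spec: QuestionnaireSpec,
    *,
    responder_flags: dict[str, bool],
    n_boot: int = 2000,
    seed: int | None = None,
    listwise: bool = False,
) -> dict[str, dict[str, AlphaEstimate | None]]:
    """Per-scale, per-arm alpha estimates with bootstrap CIs.

    Scales are the six dimensions plus the global 28-item scale; the n for
    a scale is the number of responders whose corresponding score is
    defined.  An arm where alpha is not estimable (fewer than 2 eligible
    patients, or zero variance) is reported as ``None``.
    """
    scales = list(spec.dimension_names) + [GLOBAL_SCALE]
    table: dict[str, dict[str, AlphaEstimate | None]] = {}
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    for scale in scales:
        table[scale] = {}
        for arm in ARMS:
            arm_records = [r for r in records if r.arm == arm]
            m = item_matrix(arm_records, spec, scale, responder_flags)
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            try:
                a = cronbach_alpha(m, listwise=listwise)
            except (ValueError, DegenerateScaleError):
                table[scale][arm] = None
                continue
            lo, hi = bootstrap_ci(
                lambda d: cronbach_alpha(d, listwise=listwise),
                m,
                n_boot=n_boot,
                seed=sub_seed,
            )
            table[scale][arm] = AlphaEstimate(
                alpha=a,
                ci_low=lo,
                ci_high=hi,
                n_patients=m.shape[0],
                k_items=m.shape[1],
                n_boot=n_boot,
                seed=sub_seed,
            )
    return table
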