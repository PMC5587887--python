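"""Synthetic two-arm satisfaction cohorts.

No individual-level data from the trial this package models are public, so
every downstream stage is exercised on simulated cohorts that reproduce
the trial's statistical structure: 1:1 randomization to an internet and a
telephone arm, arm-dependent probability of returning the questionnaire
(~0.39 vs ~0.88), ordinal item answers driven by a correlated Gaussian
latent satisfaction per dimension with an arm-level shift, injection of
nonrelevancy / don't-know / refusal codes, and arm-dependent completion
delays (long-tailed for self-completion online, concentrated around the
scheduled day-7 call for telephone).

Item model
----------
For patient *i* and item *j* of dimension *d*::

    X_ij = mu[arm][d] + sd * (sqrt(rho) * U_id + sqrt(1 - rho) * e_ij)

with ``U_id, e_ij ~ N(0,1)`` i.i.d., giving every pair of items in a
dimension latent correlation ``rho`` (``within_dim_corr``).  Four fixed
increasing cutpoints bin ``X_ij`` into the ordinal codes 1..5.  Because
the marginal of ``X_ij`` is Normal(mu, sd^2), the expected valued score of
an item is an analytic, strictly increasing function of ``mu``; the
default calibration inverts that link so the expected per-dimension means
match the published per-arm score table.

Randomness comes from a single :class:`numpy.random.Generator` (PCG64)
seeded from the config, so a seed reproduces a cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .io import read_cohort, write_cohort  # noqa: F401  (cohort file round-trip)
from .questionnaire import QuestionnaireSpec, default_isatis_spec
from .scoring import ARMS, PatientRecord

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "generate_cohort",
    "default_trial_calibration",
    "effect_size_calibration",
    "expected_item_score",
    "solve_latent_mean",
    "global_score_moments",
    "write_cohort",
    "read_cohort",
    "write_truth",
]

DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)
NONRELEVANCY_POOL = (0, 6, 7, 8)

#: published per-arm dimension means used as calibration targets
CALIBRATION_TARGET_MEANS = {
    "internet": {
        "global_care": 70.67,
        "information": 59.62,
        "communication": 67.42,
        "behavior": 87.49,
        "room_convenience": 61.03,
        "catering": 45.77,
    },
    "telephone": {
        "global_care": 72.15,
        "information": 65.01,
        "communication": 74.58,
        "behavior": 92.14,
        "room_convenience": 60.97,
        "catering": 45.70,
    },
}

#: observed responders / LOS-eligible patients per arm
RESPONSE_RATES = {"internet": 154 / 392, "telephone": 344 / 389}

#: baseline covariate frequencies (whole-cohort column of the trial's table)
COVARIATE_FREQS = {
    "sex": {"male": 0.494, "female": 0.506},
    "relationship": {"alone": 0.438, "couple": 0.562},
    "education": {
        "lower_secondary": 0.113,
        "upper_secondary": 0.320,
        "postsecondary": 0.145,
        "bachelor_plus": 0.422,
    },
    "activity": {"nonworking": 0.412, "employed": 0.588},
    "insurance": {
        "precarious": 0.038,
        "compulsory_only": 0.051,
        "private_complementary": 0.911,
    },
}


class SimConfigError(ValueError):
    """Invalid simulation configuration; raised before any sampling."""


@dataclass
class SimConfig:
    """Cohort generator configuration; defaults must be overridden per study.

    ``latent_means`` maps arm -> dimension -> latent mean on the N(0,1)
    noise scale; ``delay_model`` maps arm -> parameter dict with a
    ``kind`` of ``lognormal`` (keys ``median``, ``sigma``) or
    ``shifted_poisson`` (keys ``offset``, ``lam``).
    """

    n_per_arm: dict[str, int]
    response_prob: dict[str, float]
    latent_means: dict[str, dict[str, float]]
    latent_sd: float = 1.0
    within_dim_corr: float = 0.55
    item_thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS
    nonrel_prob: dict[str, float] = field(
        default_factory=lambda: {a: 0.0 for a in ARMS}
    )
    dontknow_prob: float = 0.0
    refuse_prob: float = 0.0
    not_administered_prob: float = 0.0
    delay_model: dict[str, dict] = field(
        default_factory=lambda: {
            a: {"kind": "lognormal", "median": 7.0, "sigma": 0.5} for a in ARMS
        }
    )
    los_model: dict = field(
        default_factory=lambda: {
            "kind": "lognormal", "median": 5.0, "sigma": 0.9, "min": 2, "max": 60,
        }
    )
    covariate_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in COVARIATE_FREQS.items()}
    )
    age_model: dict = field(
        default_factory=lambda: {"mean": 51.5, "sd": 19.0, "min": 19, "max": 97}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for arm in ARMS:
            if arm not in self.n_per_arm or self.n_per_arm[arm] < 0:
                raise SimConfigError(f"n_per_arm[{arm!r}] must be >= 0")
            p = self.response_prob.get(arm)
            if p is None or not 0 <= p <= 1:
                raise SimConfigError(f"response_prob[{arm!r}] must be in [0,1]")
            if not 0 <= self.nonrel_prob.get(arm, 0.0) <= 1:
                raise SimConfigError(f"nonrel_prob[{arm!r}] must be in [0,1]")
            if arm not in self.latent_means:
                raise SimConfigError(f"latent_means missing arm {arm!r}")
        for p in (self.dontknow_prob, self.refuse_prob, self.not_administered_prob):
            if not 0 <= p <= 1:
                raise SimConfigError("all probabilities must lie in [0,1]")
        if self.latent_sd <= 0:
            raise SimConfigError("latent_sd must be positive")
        if not 0 <= self.within_dim_corr < 1:
            raise SimConfigError("within_dim_corr must be in [0,1)")
        t = self.item_thresholds
        if len(t) != 4 or any(b <= a for a, b in zip(t, t[1:])):
            raise SimConfigError("item_thresholds must be 4 strictly increasing cutpoints")


@dataclass
class SyntheticCohort:
    """Generated records plus the ground truth needed for recovery tests."""

    records: list[PatientRecord]
    truth: dict


# ---------------------------------------------------------------------
# analytic latent -> score link

def _bin_probs(mu: float, sd: float, thresholds: Sequence[float]) -> np.ndarray:
    """Marginal probabilities of the ordinal codes 1..5."""
    z = (np.asarray(thresholds, dtype=float) - mu) / sd
    cdf = np.concatenate([[0.0], stats.norm.cdf(z), [1.0]])
    return np.diff(cdf)


def expected_item_score(
    mu: float, sd: float = 1.0, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> float:
    """Expected valued score (0..100) of an item with latent mean ``mu``."""
    values = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
    return float(_bin_probs(mu, sd, thresholds) @ values)


def solve_latent_mean(
    target_score: float,
    sd: float = 1.0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> float:
    """Latent mean whose expected item score equals ``target_score``."""
    if not 0 < target_score < 100:
        raise SimConfigError("target score must lie strictly between 0 and 100")
    return float(
        optimize.brentq(
            lambda m: expected_item_score(m, sd, thresholds) - target_score,
            -15.0, 15.0, xtol=1e-10,
        )
    )


def _pair_joint(mu: float, sd: float, rho: float, thresholds: Sequence[float]):
    """Joint 5x5 code distribution of two items sharing a dimension latent."""
    z = (np.asarray(thresholds, dtype=float) - mu) / sd
    grid = np.concatenate([[-np.inf], z, [np.inf]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    F = np.zeros((6, 6))
    phi = stats.norm.cdf(z)
    for a in range(6):
        for b in range(6):
            if grid[a] == -np.inf or grid[b] == -np.inf:
                F[a, b] = 0.0
            elif grid[a] == np.inf and grid[b] == np.inf:
                F[a, b] = 1.0
            elif grid[a] == np.inf:
                F[a, b] = phi[b - 1]
            elif grid[b] == np.inf:
                F[a, b] = phi[a - 1]
            else:
                F[a, b] = float(mvn.cdf([grid[a], grid[b]]))
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


def global_score_moments(
    latent_means: dict[str, float],
    spec: QuestionnaireSpec | None = None,
    sd: float = 1.0,
    rho: float = 0.55,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[float, float]:
    """Analytic mean and variance of the global score with all items valued.

    The global score is the mean of the valued item scores; items in the
    same dimension share the dimension latent (correlation ``rho``), items
    of different dimensions are independent.
    """
    spec = spec or default_isatis_spec()
    values = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
    total_items = sum(len(spec.items_of(d)) for d in spec.dimension_names)
    mean = 0.0
    var = 0.0
    for dim in spec.dimension_names:
        k = len(spec.items_of(dim))
        mu = latent_means[dim]
        p = _bin_probs(mu, sd, thresholds)
        ev = float(p @ values)
        ev2 = float(p @ values**2)
        v_item = ev2 - ev**2
        joint = _pair_joint(mu, sd, rho, thresholds)
        cov_pair = float(values @ joint @ values) - ev**2
        mean += k * ev
        var += k * v_item + k * (k - 1) * cov_pair
    return mean / total_items, var / total_items**2


# ---------------------------------------------------------------------
# calibrations

def default_trial_calibration(seed: int = 0) -> SimConfig:
    """Config calibrated to the published trial marginals.

    Response probabilities 154/392 and 344/389; per-arm per-dimension
    latent means inverted from the published score table (catering lowest
    around 46, behavior of providers highest around 88-92); covariate
    frequencies from the baseline table; internet completion delays
    long-tailed around a median of 6 days, telephone delays concentrated
    at the scheduled day-7 call; nonrelevancy/refusal rates set so the
    expected per-responder count of non-valued answers matches the
    published bucket distribution (about 4.3/28 internet, 6.3/28
    telephone).
    """
    latent_means = {
        arm: {
            dim: solve_latent_mean(target)
            for dim, target in CALIBRATION_TARGET_MEANS[arm].items()
        }
        for arm in ARMS
    }
    return SimConfig(
        n_per_arm={"internet": 392, "telephone": 389},
        response_prob=dict(RESPONSE_RATES),
        latent_means=latent_means,
        within_dim_corr=0.55,
        nonrel_prob={"internet": 0.139, "telephone": 0.208},
        dontknow_prob=0.010,
        refuse_prob=0.005,
        not_administered_prob=0.005,
        delay_model={
            "internet": {"kind": "lognormal", "median": 6.0, "sigma": 1.0},
            "telephone": {"kind": "shifted_poisson", "offset": 7.0, "lam": 0.65},
        },
        seed=seed,
    )


def effect_size_calibration(
    d: float,
    n_per_arm: dict[str, int],
    seed: int = 0,
    rho: float = 0.55,
) -> SimConfig:
    """Config with a prescribed standardized global-score arm effect.

    Both arms start from the telephone-arm calibration; every internet
    dimension latent mean is shifted by a common delta solved (via the
    analytic score moments) so that the expected Cohen d of the global
    score, internet minus telephone, equals ``d``.  Response probability
    is 1 and no nonrelevancy codes are injected, so every patient has a
    defined global score.
    """
    base = {
        dim: solve_latent_mean(t)
        for dim, t in CALIBRATION_TARGET_MEANS["telephone"].items()
    }
    n1, n2 = n_per_arm["internet"], n_per_arm["telephone"]
    m0, v0 = global_score_moments(base, rho=rho)

    def gap(delta: float) -> float:
        shifted = {k: v + delta for k, v in base.items()}
        m1, v1 = global_score_moments(shifted, rho=rho)
        s_pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v0) / (n1 + n2 - 2))
        return (m1 - m0) / s_pooled - d

    delta = float(optimize.brentq(gap, -3.0, 3.0, xtol=1e-8))
    return SimConfig(
        n_per_arm=dict(n_per_arm),
        response_prob={a: 1.0 for a in ARMS},
        latent_means={
            "internet": {k: v + delta for k, v in base.items()},
            "telephone": dict(base),
        },
        within_dim_corr=rho,
        seed=seed,
    )


# ---------------------------------------------------------------------
# sampling

def _draw_delay(rng: np.random.Generator, model: dict, n: int) -> np.ndarray:
    kind = model.get("kind")
    if kind == "lognormal":
        raw = rng.lognormal(np.log(model["median"]), model["sigma"], size=n)
        return np.maximum(np.round(raw), 0.0)
    if kind == "shifted_poisson":
        return model["offset"] + rng.poisson(model["lam"], size=n).astype(float)
    raise SimConfigError(f"unknown delay model kind {kind!r}")


def _draw_los(rng: np.random.Generator, model: dict, n: int) -> np.ndarray:
    if model.get("kind") != "lognormal":
        raise SimConfigError(f"unknown LOS model kind {model.get('kind')!r}")
    raw = np.round(rng.lognormal(np.log(model["median"]), model["sigma"], size=n))
    return np.clip(raw, model.get("min", 0), model.get("max", 365)).astype(int)


def _draw_categorical(
    rng: np.random.Generator, freqs: dict[str, float], n: int
) -> np.ndarray:
    levels = list(freqs)
    p = np.asarray([freqs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def generate_cohort(
    cfg: SimConfig, spec: QuestionnaireSpec | None = None
) -> SyntheticCohort:
    """Sample a cohort; deterministic given ``cfg.seed``.

    Nonresponders carry no answers and no completion delay.  Responder
    item codes start from the thresholded latent and are then replaced,
    independently per item, by a nonrelevancy code (uniform over
    {0, 6, 7, 8}) with probability ``nonrel_prob[arm]``, by 9 or 10 with
    ``dontknow_prob`` / ``refuse_prob``, or dropped entirely (structural
    missingness, as for items only administered to some patients) with
    ``not_administered_prob``.  The four excluded items receive codes from
    an uncorrelated latent at the mean of the dimension means.
    """
    cfg.validate()
    spec = spec or default_isatis_spec()
    rng = np.random.default_rng(cfg.seed)
    dims = spec.dimension_names
    item_dim_idx = {
        item: di for di, d in enumerate(dims) for item in spec.items_of(d)
    }
    all_items = spec.all_items
    rho = cfg.within_dim_corr
    a_shared, a_noise = np.sqrt(rho), np.sqrt(1.0 - rho)

    records: list[PatientRecord] = []
    latent_truth: dict[str, dict[str, float]] = {}
    for arm in ARMS:
        n = cfg.n_per_arm[arm]
        if n == 0:
            continue
        los = _draw_los(rng, cfg.los_model, n)
        covs = {
            name: _draw_categorical(rng, freqs, n)
            for name, freqs in cfg.covariate_freqs.items()
        }
        age = np.clip(
            np.round(rng.normal(cfg.age_model["mean"], cfg.age_model["sd"], n)),
            cfg.age_model["min"], cfg.age_model["max"],
        )
        responds = rng.random(n) < cfg.response_prob[arm]

        mu = np.array([cfg.latent_means[arm][d] for d in dims])
        mu_excl = float(mu.mean())
        shared = rng.standard_normal((n, len(dims)))
        noise = rng.standard_normal((n, len(all_items)))
        thresholds = np.asarray(cfg.item_thresholds)

        x = np.empty((n, len(all_items)))
        for j, item in enumerate(all_items):
            if item in item_dim_idx:
                di = item_dim_idx[item]
                x[:, j] = mu[di] + cfg.latent_sd * (
                    a_shared * shared[:, di] + a_noise * noise[:, j]
                )
            else:  # excluded item: independent latent
                x[:, j] = mu_excl + cfg.latent_sd * noise[:, j]
        codes = 1 + np.searchsorted(thresholds, x)

        u = rng.random((n, len(all_items)))
        nonrel_draw = rng.integers(0, len(NONRELEVANCY_POOL), (n, len(all_items)))
        p_nr = cfg.nonrel_prob[arm]
        p_dk = p_nr + cfg.dontknow_prob
        p_rf = p_dk + cfg.refuse_prob
        pool = np.asarray(NONRELEVANCY_POOL)
        codes = np.where(u < p_nr, pool[nonrel_draw], codes)
        codes = np.where((u >= p_nr) & (u < p_dk), 9, codes)
        codes = np.where((u >= p_dk) & (u < p_rf), 10, codes)
        administered = rng.random((n, len(all_items))) >= cfg.not_administered_prob

        delays = _draw_delay(rng, cfg.delay_model[arm], n)

        for i in range(n):
            pid = f"{arm[:3]}-{i + 1:04d}"
            if responds[i]:
                responses = {
                    item: int(codes[i, j])
                    for j, item in enumerate(all_items)
                    if administered[i, j]
                }
                delay: float | None = float(delays[i])
                latent_truth[pid] = {
                    d: float(mu[di] + cfg.latent_sd * a_shared * shared[i, di])
                    for di, d in enumerate(dims)
                }
            else:
                responses, delay = {}, None
            records.append(
                PatientRecord(
                    patient_id=pid,
                    arm=arm,
                    los_days=int(los[i]),
                    sex=str(covs["sex"][i]),
                    age_years=float(age[i]),
                    relationship=str(covs["relationship"][i]),
                    education=str(covs["education"][i]),
                    activity=str(covs["activity"][i]),
                    insurance=str(covs["insurance"][i]),
                    delay_days=delay,
                    responses=responses,
                )
            )

    truth = {
        "config": asdict(cfg),
        "latent_means": {arm: dict(cfg.latent_means[arm]) for arm in ARMS},
        "patient_latents": latent_truth,
        "rng": "numpy PCG64 via default_rng(seed)",
    }
    return SyntheticCohort(records=records, truth=truth)


def write_truth(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write the ground-truth sidecar (JSON) for parameter-recovery tests."""
    Path(path).write_text(json.dumps(cohort.truth, indent=2, default=float))
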