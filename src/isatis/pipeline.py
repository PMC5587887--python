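"""Orchestration: simulate or load a cohort, score it, estimate
reliability, run the between-arm comparisons, and emit report tables.

The report bundle mirrors the reporting of a two-arm survey-mode trial:
a participant-flow table (enrolled, stay-eligible, responders with rates,
score-eligible per arm), a baseline characteristics table, an
internal-consistency (Cronbach alpha) table, a satisfaction-score
comparison table, a nonrelevancy bucket table, and a machine-readable
JSON bundle carrying every number plus the seeds that produced it.

All randomness flows from a single root seed, split per stage with
:class:`numpy.random.SeedSequence`; the per-stage seeds are logged in the
report so any stage can be replayed in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .inference import compare_arms
from .io import read_cohort, write_cohort
from .questionnaire import QuestionnaireSpec, default_isatis_spec
from .reliability import alpha_table
from .scoring import (
    ARMS,
    PatientRecord,
    ScoreSet,
    bucket_counts,
    score_cohort,
)
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger("isatis")

__all__ = ["RunConfig", "run", "summarize_baseline", "round_half_up"]


class ConfigError(ValueError):
    """Invalid run configuration."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, the convention used in the report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """End-to-end run: exactly one of ``input_path`` / ``sim_config``."""

    input_path: str | None = None
    sim_config: SimConfig | None = None
    spec: QuestionnaireSpec | None = None
    los_filter: bool = True
    min_los_nights: int = 2
    completed_definition: str = "any"
    n_boot: int = 2000
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim_config is None):
            raise ConfigError("provide exactly one of input_path / sim_config")
        if self.n_boot < 1 or self.n_perm < 1:
            raise ConfigError("n_boot and n_perm must be >= 1")


def summarize_baseline(
    records: Sequence[PatientRecord], scores: Sequence[ScoreSet]
) -> dict:
    """Baseline characteristics by responder status and arm.

    Counts and column percentages for each categorical covariate, and
    median with interquartile range for length of stay, age, and (among
    responders) completion delay.  Percentages are computed over the
    column totals and rounded half-up to one decimal.
    """
    responder = {s.patient_id: s.responder for s in scores}
    in_population = set(responder)
    cols = {"total": [r for r in records if r.patient_id in in_population]}
    for arm in ARMS:
        cols[f"responders_{arm}"] = [
            r for r in cols["total"] if r.arm == arm and responder[r.patient_id]
        ]
        cols[f"nonresponders_{arm}"] = [
            r for r in cols["total"] if r.arm == arm and not responder[r.patient_id]
        ]

    def med_iqr(values: list[float]) -> dict | None:
        if not values:
            return None
        q1, q2, q3 = np.percentile(values, [25, 50, 75])
        return {"median": float(q2), "iqr": [float(q1), float(q3)]}

    categoricals = ("sex", "relationship", "education", "activity", "insurance")
    out: dict = {"n": {name: len(rs) for name, rs in cols.items()}}
    for cov in categoricals:
        out[cov] = {}
        for name, rs in cols.items():
            levels: dict[str, int] = {}
            for r in rs:
                levels[getattr(r, cov)] = levels.get(getattr(r, cov), 0) + 1
            out[cov][name] = {
                lvl: {
                    "n": cnt,
                    "pct": round_half_up(100.0 * cnt / len(rs)) if rs else None,
                }
                for lvl, cnt in sorted(levels.items())
            }
    out["los_days"] = {
        name: med_iqr([float(r.los_days) for r in rs]) for name, rs in cols.items()
    }
    out["age_years"] = {
        name: med_iqr([float(r.age_years) for r in rs]) for name, rs in cols.items()
    }
    out["delay_days"] = {
        name: med_iqr(
            [float(r.delay_days) for r in rs if r.delay_days is not None]
        )
        for name, rs in cols.items()
        if name.startswith("responders_")
    }
    return out


def _flow_with_rates(flow: dict) -> dict:
    out = {}
    for arm, f in flow.items():
        g = dict(f)
        g["response_rate_pct"] = (
            round_half_up(100.0 * f["responders"] / f["los_eligible"])
            if f["los_eligible"]
            else None
        )
        out[arm] = g
    return out


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the report."""
    spec = cfg.spec or default_isatis_spec()
    root = np.random.SeedSequence(cfg.seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(("simulate", "reliability", "inference"), root.spawn(3))
    }

    if cfg.sim_config is not None:
        sim = cfg.sim_config
        logger.info("simulating cohort (seed %d)", sim.seed)
        cohort = generate_cohort(sim, spec)
        records = cohort.records
    else:
        logger.info("reading cohort from %s", cfg.input_path)
        records = read_cohort(cfg.input_path, spec)

    scores, flow = score_cohort(
        records,
        spec,
        los_filter=cfg.los_filter,
        min_los_nights=cfg.min_los_nights,
        completed_definition=cfg.completed_definition,
    )
    for arm, f in flow.items():
        if f["los_excluded"]:
            logger.info(
                "%s arm: %d patients excluded by the minimum-stay rule",
                arm, f["los_excluded"],
            )

    population = [
        r for r in records
        if not cfg.los_filter or r.los_days >= cfg.min_los_nights
    ]
    baseline = summarize_baseline(population, scores)
    buckets = bucket_counts(population, spec, cfg.completed_definition)
    bucket_pct = {
        arm: {
            b: {
                "n": n,
                "pct": round_half_up(100.0 * n / max(sum(d.values()), 1)),
            }
            for b, n in d.items()
        }
        for arm, d in ((a, buckets[a]) for a in ARMS)
    }

    responder_flags = {s.patient_id: s.responder for s in scores}
    alphas = alpha_table(
        population,
        spec,
        responder_flags=responder_flags,
        n_boot=cfg.n_boot,
        seed=stage_seed["reliability"],
    )
    alpha_report = {
        scale: {
            arm: (
                None
                if est is None
                else {
                    "alpha": est.alpha,
                    "ci": [est.ci_low, est.ci_high],
                    "n": est.n_patients,
                    "k": est.k_items,
                }
            )
            for arm, est in by_arm.items()
        }
        for scale, by_arm in alphas.items()
    }

    try:
        comparison = compare_arms(
            population,
            scores,
            spec,
            n_boot=cfg.n_boot,
            n_perm=cfg.n_perm,
            seed=stage_seed["inference"],
        )
    except ValueError as exc:
        logger.warning("between-arm comparison skipped: %s", exc)
        comparison = {"note": f"not estimable: {exc}", "scales": {}}

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": stage_seed,
        "config": {
            "los_filter": cfg.los_filter,
            "min_los_nights": cfg.min_los_nights,
            "completed_definition": cfg.completed_definition,
            "n_boot": cfg.n_boot,
            "n_perm": cfg.n_perm,
        },
        "flow": _flow_with_rates(flow),
        "baseline": baseline,
        "nonrelevancy_buckets": bucket_pct,
        "alpha": alpha_report,
        "comparison": comparison,
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
        )
        _write_scores_csv(scores, spec, out / "scores.csv")
        _write_alpha_tsv(alpha_report, out / "alpha.tsv")
        _write_comparison_tsv(comparison, out / "comparison.tsv")
        if cfg.sim_config is not None:
            write_cohort(records, out / "cohort.csv", spec)
    return report


def _write_scores_csv(scores, spec, path: Path) -> None:
    dims = spec.dimension_names
    lines = [
        ",".join(
            ["patient_id", "arm", "responder", *dims, "global",
             "n_valued", "n_nonrelevancy"]
        )
    ]
    fmt = lambda v: "" if v is None else f"{v:.6g}"  # noqa: E731
    for s in scores:
        lines.append(
            ",".join(
                [
                    s.patient_id,
                    s.arm,
                    str(int(s.responder)),
                    *[fmt(s.dimension_scores[d]) for d in dims],
                    fmt(s.global_score),
                    str(s.n_valued_items),
                    str(s.n_nonrelevancy),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_alpha_tsv(alpha_report: dict, path: Path) -> None:
    lines = ["scale\tarm\talpha\tci_low\tci_high\tn"]
    for scale, by_arm in alpha_report.items():
        for arm, est in by_arm.items():
            if est is None:
                lines.append(f"{scale}\t{arm}\tNA\tNA\tNA\tNA")
            else:
                lines.append(
                    f"{scale}\t{arm}\t{est['alpha']:.3f}\t{est['ci'][0]:.3f}"
                    f"\t{est['ci'][1]:.3f}\t{est['n']}"
                )
    path.write_text("\n".join(lines) + "\n")


def _write_comparison_tsv(comparison: dict, path: Path) -> None:
    lines = [
        "scale\tmean_internet\tn_internet\tmean_telephone\tn_telephone"
        "\tdifference\tdiff_ci_low\tdiff_ci_high\tpermutation_p\teffect_d"
    ]
    for scale, e in comparison["scales"].items():
        if "mean" not in e:
            lines.append(f"{scale}\tNA\t{e['n']['internet']}\tNA\t{e['n']['telephone']}\tNA\tNA\tNA\tNA\tNA")
            continue
        es = e["effect_size"]
        lines.append(
            "\t".join(
                [
                    scale,
                    f"{e['mean']['internet']:.2f}",
                    str(e["n"]["internet"]),
                    f"{e['mean']['telephone']:.2f}",
                    str(e["n"]["telephone"]),
                    f"{e['difference']:.2f}",
                    f"{e['difference_ci'][0]:.2f}",
                    f"{e['difference_ci'][1]:.2f}",
                    f"{e['permutation_p']:.4g}",
                    "NA" if es is None else f"{es['d']:.3f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
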