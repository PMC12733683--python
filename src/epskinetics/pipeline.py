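"""Pipeline orchestration: simulate -> fit -> report.

``run_pipeline`` ties the modules into one reproducible run: generate (or
load) replicated time courses, fit the logistic stage and the
Luedeking-Piret stage per condition, derive the summary quantities
(q_P,max, growth-association class, the mu_max ratio between conditions),
and emit a machine-readable JSON report plus a human-readable text one.

Report schema (stable field names), top level:
  version, seed, config, conditions.  Each conditions[<label>] holds
  growth: {X0, Xmax, mu_max, r_squared, converged, n_obs, flags},
  product: {P0, alpha, beta, r_squared, converged, n_obs, flags},
  derived: {qp_max, association_class}.  When exactly two conditions are
  present the top level adds mu_max_ratio = {numerator, denominator, value}
  with the lexicographically first condition in the numerator.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from dataclasses import asdict, dataclass, field, replace

from . import __version__
from .fitting import (
    FITTED_CLASSIFICATION_TOL,
    FitResult,
    fit_logistic,
    fit_luedeking_piret,
)
from .io import read_study_csv, write_timecourse_csv
from .kinetics import classify_association, max_specific_production_rate
from .simulate import Scenario, TimeCourse, default_scenarios, generate_study

__all__ = ["RunConfig", "KineticsReport", "run_pipeline"]

log = logging.getLogger("epskinetics")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input source: ``input_csv`` (fit existing data) or the
    built-in two-condition scenario set (``use_default_scenarios=True``,
    which simulates first and requires a seed).
    """

    outdir: str
    input_csv: str | None = None
    use_default_scenarios: bool = False
    seed: int | None = None
    noise_cv: float = 0.03
    truncate_at_peak: bool = False
    average_replicates: bool = False
    # coefficients below this magnitude count as zero when classifying
    # *fitted* estimates (see fitting.FITTED_CLASSIFICATION_TOL)
    classification_tol: float = FITTED_CLASSIFICATION_TOL
    write_text_report: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (not self.use_default_scenarios):
            raise ValueError(
                "exactly one input source: input_csv or use_default_scenarios"
            )
        if self.use_default_scenarios and self.seed is None:
            raise ValueError("seed is required when simulation is enabled")


def _fit_block(fr: FitResult) -> dict:
    p = asdict(fr.params)
    p.update(
        r_squared=fr.r_squared,
        converged=fr.converged,
        n_obs=fr.n_obs,
        flags=list(fr.flags),
    )
    return p


@dataclass
class KineticsReport:
    """Structured results of one pipeline run."""

    version: str
    seed: int | None
    config: dict
    conditions: dict[str, dict] = field(default_factory=dict)
    mu_max_ratio: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "conditions": self.conditions,
        }
        if self.mu_max_ratio is not None:
            out["mu_max_ratio"] = self.mu_max_ratio
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [f"epskinetics kinetics report (v{self.version}, seed={self.seed})"]
        for label, block in sorted(self.conditions.items()):
            g, p, d = block["growth"], block["product"], block["derived"]
            lines += [
                "",
                f"condition: {label}",
                f"  logistic fit:  X0={g['X0']:.4g}  Xmax={g['Xmax']:.4g}  "
                f"mu_max={g['mu_max']:.5g} 1/h  R^2={g['r_squared']:.4f}",
                f"  Luedeking-Piret fit:  P0={p['P0']:.4g}  alpha={p['alpha']:.5g}  "
                f"beta={p['beta']:.5g}  R^2={p['r_squared']:.4f}",
                f"  q_P,max = {d['qp_max']:.5g} 1/h   "
                f"association: {d['association_class']}",
            ]
        if self.mu_max_ratio is not None:
            r = self.mu_max_ratio
            lines.append(
                f"\nmu_max ratio {r['numerator']}/{r['denominator']} = "
                f"{r['value']:.4g}"
            )
        return "\n".join(lines) + "\n"


def _fit_condition(tc: TimeCourse, cfg: RunConfig) -> dict:
    log.info("fitting condition %s (%d observations)", tc.condition, tc.n_obs)
    growth = fit_logistic(
        tc,
        truncate_at_peak=cfg.truncate_at_peak,
        average_replicates=cfg.average_replicates,
    )
    product = fit_luedeking_piret(
        tc, growth.params, average_replicates=cfg.average_replicates
    )
    qp_max = max_specific_production_rate(growth.params, product.params)
    assoc = classify_association(product.params, tol=cfg.classification_tol)
    return {
        "growth": _fit_block(growth),
        "product": _fit_block(product),
        "derived": {"qp_max": qp_max, "association_class": assoc.value},
    }


def run_pipeline(cfg: RunConfig) -> KineticsReport:
    """Execute the configured stages and write report files to ``cfg.outdir``.

    Raises ``PipelineStageError`` with the failing stage name attached.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    try:
        if cfg.use_default_scenarios:
            log.info("simulate: default two-condition study, seed=%s", cfg.seed)
            scenarios = default_scenarios(noise_cv=cfg.noise_cv)
            study = generate_study(scenarios, seed=cfg.seed)
            for label, tc in study.items():
                write_timecourse_csv(tc, os.path.join(cfg.outdir, f"{label}.csv"))
        else:
            log.info("load: %s", cfg.input_csv)
            study = read_study_csv(cfg.input_csv)
    except Exception as exc:
        raise PipelineStageError("simulate/load", exc) from exc

    report = KineticsReport(
        version=__version__, seed=cfg.seed, config=asdict(cfg)
    )
    try:
        for label in sorted(study):
            report.conditions[label] = _fit_condition(study[label], cfg)
    except Exception as exc:
        raise PipelineStageError("fit", exc) from exc

    if len(report.conditions) == 2:
        (la, a), (lb, b) = sorted(report.conditions.items())
        report.mu_max_ratio = {
            "numerator": la,
            "denominator": lb,
            "value": a["growth"]["mu_max"] / b["growth"]["mu_max"],
        }

    try:
        with open(
            os.path.join(cfg.outdir, "report.json"), "w", encoding="utf-8"
        ) as fh:
            fh.write(report.to_json())
        if cfg.write_text_report:
            with open(
                os.path.join(cfg.outdir, "report.txt"), "w", encoding="utf-8"
            ) as fh:
                fh.write(report.to_text())
    except Exception as exc:
        raise PipelineStageError("report", exc) from exc
    log.info("report written to %s", cfg.outdir)
    return report


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
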