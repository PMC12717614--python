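"""End-to-end pipeline: cohort -> decisions -> accuracy -> projections -> report.

A :class:`PipelineConfig` names the input (a cohort CSV, a simulation spec,
or the deterministic table-exact fixture), the rules and strata to evaluate,
and the CI method. :func:`run_pipeline` returns a :class:`ComparisonReport`
whose JSON and Markdown renderings carry identical numbers (all percentage
formatting is centralized in :mod:`csirules.diagnostics`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from . import __version__
from .diagnostics import CIMethod, accuracy_report, round_half_up
from .projection import projection_report
from .records import PatientRecord, read_cohort, stratify_by_age, write_cohort
from .rules import DEFAULT_POLICY, Rule, RulePolicy, classify_cohort, decisions_frame
from .simulate import DEFAULT_CONFIG, GeneratorConfig, build_table_exact_fixture, generate_cohort

logger = logging.getLogger(__name__)

RULE_ORDER = (Rule.PECARN, Rule.NEXUS, Rule.CCR)
STRATA = ("all", "age_0_8", "age_9_17")


class SimulationSpec(BaseModel):
    n: int = 22430
    seed: int = DEFAULT_CONFIG.seed
    overrides: dict = Field(default_factory=dict)

    def to_generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(**{"n": self.n, "seed": self.seed, **self.overrides})


class PipelineConfig(BaseModel):
    """Run configuration (loadable from YAML)."""

    input_path: Optional[Path] = None
    simulate: Optional[SimulationSpec] = None
    fixture: bool = False
    rules: list[Rule] = Field(default_factory=lambda: list(RULE_ORDER))
    strata: list[str] = Field(default_factory=lambda: list(STRATA))
    ci_method: CIMethod = CIMethod.WALD
    stratum_specific_ratio: bool = True
    nexus_preverbal_exception: bool = True
    nexus_distracting_from_substantial: bool = True

    @model_validator(mode="after")
    def _exactly_one_input(self):
        sources = sum(
            1 for s in (self.input_path, self.simulate, True if self.fixture else None)
            if s is not None
        )
        if sources != 1:
            raise ValueError(
                "exactly one of input_path, simulate, fixture must be given"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def policy(self) -> RulePolicy:
        return RulePolicy(
            nexus_preverbal_exception=self.nexus_preverbal_exception,
            nexus_distracting_from_substantial=self.nexus_distracting_from_substantial,
        )


@dataclass
class ComparisonReport:
    """Accuracy and projection results for every requested rule and stratum."""

    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        p = self.payload
        lines = [
            "# CSI prediction-rule comparison",
            "",
            f"Cohort: n={p['cohort']['n']}, CSI prevalence "
            f"{p['cohort']['csi_prevalence_pct']}% "
            f"(0-8 y: {p['cohort']['n_age_0_8']}; 9-17 y: {p['cohort']['n_age_9_17']})",
            "",
            "## Diagnostic accuracy",
            "",
            "| Stratum | Rule | TP | FP | FN | TN | Sensitivity (95% CI) | "
            "Specificity (95% CI) | NPV (95% CI) | PPV (95% CI) | AUC |",
            "|---|---|---|---|---|---|---|---|---|---|---|",
        ]

        def ci(stat: dict) -> str:
            if stat["pct"] is None:
                return "undefined"
            return f"{stat['pct']} ({stat['ci_lower_pct']}-{stat['ci_upper_pct']})"

        for stratum in p["strata"]:
            for rule in p["rules"]:
                a = p["accuracy"][rule][stratum]
                lines.append(
                    f"| {stratum} | {rule} | {a['tp']} | {a['fp']} | {a['fn']} | "
                    f"{a['tn']} | {ci(a['sensitivity'])} | {ci(a['specificity'])} | "
                    f"{ci(a['npv'])} | {ci(a['ppv'])} | {a['auc']} |"
                )
        lines += [
            "",
            "## Imaging allocation (actual and projected)",
            "",
            "| Stratum | Rule | Cleared n (%) | Radiography n (%) | CT n (%) |",
            "|---|---|---|---|---|",
        ]
        for stratum in p["strata"]:
            for rule in ("actual", *p["rules"]):
                pr = p["projection"][rule][stratum]
                lines.append(
                    f"| {stratum} | {rule} | {pr['cleared_n']} ({pr['cleared_pct']}) | "
                    f"{pr['radiography_n']} ({pr['radiography_pct']}) | "
                    f"{pr['ct_n']} ({pr['ct_pct']}) |"
                )
        lines += ["", f"Provenance: {json.dumps(p['provenance'], sort_keys=True)}", ""]
        return "\n".join(lines)


def _load_records(config: PipelineConfig) -> tuple[list[PatientRecord], dict]:
    if config.fixture:
        return build_table_exact_fixture(), {"input": "table_exact_fixture"}
    if config.simulate is not None:
        gen = config.simulate.to_generator_config()
        prov = {
            "input": "simulation",
            "seed": gen.seed,
            "config_hash": hashlib.sha256(
                gen.model_dump_json().encode()
            ).hexdigest()[:16],
        }
        return generate_cohort(gen), prov
    return read_cohort(config.input_path), {"input": str(config.input_path)}


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Classify, evaluate and project; deterministic given the seed."""
    t0 = time.perf_counter()
    records, provenance = _load_records(config)
    logger.info("loaded %d records in %.2fs", len(records), time.perf_counter() - t0)
    policy = config.policy()

    young, old = stratify_by_age(records)
    csi_n = sum(r.csi_present for r in records)
    payload: dict = {
        "cohort": {
            "n": len(records),
            "csi_n": csi_n,
            "csi_prevalence_pct": round_half_up(100 * csi_n / len(records), 1),
            "n_age_0_8": len(young),
            "n_age_9_17": len(old),
        },
        "rules": [r.value for r in config.rules],
        "strata": list(config.strata),
        "provenance": {**provenance, "tool_version": __version__},
        "accuracy": {},
        "projection": {},
    }

    t0 = time.perf_counter()
    acc = accuracy_report(records, config.rules, config.strata, config.ci_method, policy)
    for (rule, stratum), (ct, tc) in acc.items():
        stats = {}
        for name, est in (
            ("sensitivity", tc.sensitivity),
            ("specificity", tc.specificity),
            ("npv", tc.npv),
            ("ppv", tc.ppv),
        ):
            if est.defined:
                pct, lo, hi = est.as_pct()
                stats[name] = {"pct": pct, "ci_lower_pct": lo, "ci_upper_pct": hi}
            else:
                stats[name] = {"pct": None, "ci_lower_pct": None, "ci_upper_pct": None}
        payload["accuracy"].setdefault(rule, {})[stratum] = {
            "tp": ct.tp,
            "fp": ct.fp,
            "fn": ct.fn,
            "tn": ct.tn,
            **stats,
            "auc": round_half_up(tc.auc, 2) if tc.auc is not None else None,
        }
    logger.info("accuracy grid in %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    proj = projection_report(
        records, config.rules, config.strata, config.stratum_specific_ratio, policy
    )
    for (rule, stratum), pr in proj.items():
        payload["projection"].setdefault(rule, {})[stratum] = {
            "cleared_n": pr.cleared_n,
            "cleared_pct": pr.cleared_pct,
            "radiography_n": pr.radiography_n,
            "radiography_pct": pr.radiography_pct,
            "ct_n": pr.ct_n,
            "ct_pct": pr.ct_pct,
        }
    logger.info("projections in %.2fs", time.perf_counter() - t0)
    return ComparisonReport(payload)


def write_outputs(
    config: PipelineConfig, report: ComparisonReport, outdir: Path
) -> dict[str, Path]:
    """Write report.json, report.md, decisions.csv and projection.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, _ = _load_records(config)
    paths = {
        "report_json": outdir / "report.json",
        "report_md": outdir / "report.md",
        "decisions_csv": outdir / "decisions.csv",
        "projection_csv": outdir / "projection.csv",
    }
    paths["report_json"].write_text(report.to_json())
    paths["report_md"].write_text(report.to_markdown())
    import pandas as pd

    frames = [
        decisions_frame(classify_cohort(records, rule, config.policy()))
        for rule in config.rules
    ]
    pd.concat(frames, ignore_index=True).to_csv(paths["decisions_csv"], index=False)
    from .projection import projection_frame

    projection_frame(
        projection_report(
            records, config.rules, config.strata,
            config.stratum_specific_ratio, config.policy(),
        )
    ).to_csv(paths["projection_csv"], index=False)
    return paths
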