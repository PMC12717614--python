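"""Diagnostic-accuracy statistics for rule decisions.

For one rule on one cohort stratum: the 2x2 confusion table against the
reference-standard CSI status, the four test characteristics (sensitivity,
specificity, NPV, PPV) each with a 95% confidence interval, and the
single-operating-point AUC.

Every rule here operates at a single threshold (positive = any risk factor),
so its ROC consists of one point (1 - specificity, sensitivity) joined to
(0, 0) and (1, 1); the trapezoidal area is (sensitivity + specificity) / 2.

Reporting convention: proportions are percentages rounded half-up at one
decimal, AUC at two decimals. Confidence intervals default to the Wald
(normal-approximation) interval, which reproduces the published bounds for
every stratum; Wilson is available for robustness at extreme proportions.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import norm

from .records import CohortStratum, PatientRecord, stratify_by_age
from .rules import DEFAULT_POLICY, Rule, RuleDecision, RulePolicy, classify_cohort

logger = logging.getLogger(__name__)

Z_95 = float(norm.ppf(0.975))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals.

    ``round()`` uses banker's rounding; published tables round 0.05 up, so
    rounding goes through :class:`decimal.Decimal` on the shortest repr.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(p: float) -> float:
    """Proportion -> percentage, half-up at 1 decimal (table convention)."""
    return round_half_up(100.0 * p, 1)


class CIMethod(str, enum.Enum):
    WALD = "wald"
    WILSON = "wilson"


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts for one rule on one stratum."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Records the rule flagged (rule-positive, regardless of CSI)."""
        return self.tp + self.fp

    @property
    def csi_count(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its 95% CI, or undefined (zero denominator)."""

    point: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.point is not None

    def as_pct(self) -> tuple[float, float, float]:
        if not self.defined:
            raise ValueError("proportion undefined (zero denominator)")
        return (
            format_pct(self.point),
            format_pct(self.ci_lower),
            format_pct(self.ci_upper),
        )


@dataclass(frozen=True)
class TestCharacteristics:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    npv: ProportionEstimate
    ppv: ProportionEstimate
    auc: Optional[float]


def proportion_ci(
    count: int, nobs: int, method: CIMethod | str = CIMethod.WALD
) -> ProportionEstimate:
    """Binomial proportion with 95% CI, clipped to [0, 1].

    Wald: p +/- z * sqrt(p(1-p)/n). At p in {0, 1} the Wald interval
    collapses to a point; this is reported with a logged warning rather
    than silently substituting another method.
    """
    if nobs == 0:
        return ProportionEstimate(None, None, None, count, nobs)
    method = CIMethod(method)
    p = count / nobs
    if method is CIMethod.WALD:
        if p in (0.0, 1.0):
            logger.warning(
                "Wald CI degenerate at p=%g (count=%d, n=%d); interval collapses "
                "to a point — consider ci_method='wilson'",
                p,
                count,
                nobs,
            )
        half = Z_95 * math.sqrt(p * (1.0 - p) / nobs)
        lo, hi = p - half, p + half
    else:
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return ProportionEstimate(p, max(0.0, lo), min(1.0, hi), count, nobs)


def confusion_from_decisions(
    decisions: Sequence[tuple[str, RuleDecision]],
    records: Sequence[PatientRecord],
) -> ConfusionTable:
    """Cross-tabulate rule decisions against reference-standard CSI status.

    Decisions and records are aligned by ``record_id``; a mismatch between
    the two id sets is an error listing the offending ids.
    """
    truth = {r.record_id: r.csi_present for r in records}
    decided = {rid for rid, _ in decisions}
    if decided != set(truth):
        missing = sorted(set(truth) - decided)[:10]
        extra = sorted(decided - set(truth))[:10]
        raise ValueError(
            f"decision/record id mismatch: missing decisions for {missing}, "
            f"decisions without records for {extra}"
        )
    tp = fp = fn = tn = 0
    for rid, d in decisions:
        if d.positive:
            if truth[rid]:
                tp += 1
            else:
                fp += 1
        else:
            if truth[rid]:
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def auc_single_point(sensitivity: float, specificity: float) -> float:
    """Trapezoidal AUC of a one-point ROC: (sensitivity + specificity) / 2."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0


def test_characteristics(
    ct: ConfusionTable, ci_method: CIMethod | str = CIMethod.WALD
) -> TestCharacteristics:
    """Sensitivity, specificity, NPV, PPV (95% CI each) and AUC from a 2x2 table."""
    sens = proportion_ci(ct.tp, ct.tp + ct.fn, ci_method)
    spec = proportion_ci(ct.tn, ct.tn + ct.fp, ci_method)
    npv = proportion_ci(ct.tn, ct.tn + ct.fn, ci_method)
    ppv = proportion_ci(ct.tp, ct.tp + ct.fp, ci_method)
    auc = (
        auc_single_point(sens.point, spec.point)
        if sens.defined and spec.defined
        else None
    )
    return TestCharacteristics(sens, spec, npv, ppv, auc)


def _strata_map(
    records: Sequence[PatientRecord], strata: Sequence[str]
) -> Mapping[str, Sequence[PatientRecord]]:
    young, old = stratify_by_age(records)
    available = {"all": list(records), "age_0_8": young.records, "age_9_17": old.records}
    return {label: available[label] for label in strata}


def accuracy_report(
    records: Sequence[PatientRecord],
    rules: Iterable[Rule | str] = (Rule.PECARN, Rule.NEXUS, Rule.CCR),
    strata: Sequence[str] = ("all", "age_0_8", "age_9_17"),
    ci_method: CIMethod | str = CIMethod.WALD,
    policy: RulePolicy = DEFAULT_POLICY,
) -> dict[tuple[str, str], tuple[ConfusionTable, TestCharacteristics]]:
    """Full accuracy grid: (rule, stratum) -> (confusion table, characteristics)."""
    out: dict[tuple[str, str], tuple[ConfusionTable, TestCharacteristics]] = {}
    for label, subset in _strata_map(records, strata).items():
        for rule in rules:
            rule = Rule(rule)
            decisions = classify_cohort(subset, rule, policy)
            ct = confusion_from_decisions(decisions, subset)
            out[(rule.value, label)] = (ct, test_characteristics(ct, ci_method))
    return out


def accuracy_frame(report: Mapping[tuple[str, str], tuple[ConfusionTable, TestCharacteristics]]):
    """Flatten an accuracy grid into a DataFrame in published-table layout."""
    import pandas as pd

    rows = []
    for (rule, stratum), (ct, tc) in report.items():
        row = {
            "rule": rule,
            "stratum": stratum,
            "tp": ct.tp,
            "fp": ct.fp,
            "fn": ct.fn,
            "tn": ct.tn,
        }
        for name, est in (
            ("sensitivity", tc.sensitivity),
            ("specificity", tc.specificity),
            ("npv", tc.npv),
            ("ppv", tc.ppv),
        ):
            if est.defined:
                pct, lo, hi = est.as_pct()
            else:
                pct = lo = hi = float("nan")
            row[name] = pct
            row[f"{name}_ci_lower"] = lo
            row[f"{name}_ci_upper"] = hi
        row["auc"] = round_half_up(tc.auc, 2) if tc.auc is not None else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
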