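"""Actual and projected imaging rates under each prediction rule.

Each rule partitions a cohort into clinically cleared / radiography / CT.
PECARN does this directly through its tiers (high-risk factors -> CT,
CART-derived factors -> radiography). NEXUS and the CCR are binary — they
flag a child for imaging without choosing a modality — so their projected
modality mix is obtained by applying the *observed* radiography:CT ratio
among imaged children in the cohort to their rule-positive counts.

Allocation convention: the CT count is positives x ct_share rounded half
up, radiography is positives minus CT. Rounding one component and taking
the other by subtraction keeps cleared + radiography + CT = n exactly;
rounding both independently could not guarantee that.

The observed ratio is computed over radiography + CT only; children imaged
by MRI alone or by other modalities are excluded from the ratio denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .diagnostics import format_pct, round_half_up
from .records import ObservedImaging, PatientRecord, stratify_by_age
from .rules import DEFAULT_POLICY, Rule, RuleDecision, RulePolicy, Tier, classify_cohort


@dataclass(frozen=True)
class ModalityRatio:
    """Observed radiography/CT split among imaged children."""

    radiography_observed: int
    ct_observed: int

    @property
    def imaged_total(self) -> int:
        return self.radiography_observed + self.ct_observed

    @property
    def radiography_share(self) -> float:
        return self.radiography_observed / self.imaged_total

    @property
    def ct_share(self) -> float:
        return self.ct_observed / self.imaged_total


@dataclass(frozen=True)
class ImagingProjection:
    """Cleared / radiography / CT allocation for one rule on one stratum."""

    rule: str
    stratum: str
    cleared_n: int
    radiography_n: int
    ct_n: int
    modality_ratio_source: ModalityRatio | None = None

    @property
    def n(self) -> int:
        return self.cleared_n + self.radiography_n + self.ct_n

    @property
    def cleared_pct(self) -> float:
        return format_pct(self.cleared_n / self.n)

    @property
    def radiography_pct(self) -> float:
        return format_pct(self.radiography_n / self.n)

    @property
    def ct_pct(self) -> float:
        return format_pct(self.ct_n / self.n)


def observed_modality_ratio(records: Iterable[PatientRecord]) -> ModalityRatio:
    """Observed radiography/CT counts among imaged children (MRI/other excluded)."""
    rad = ct = 0
    for r in records:
        if r.observed_imaging is ObservedImaging.RADIOGRAPHY:
            rad += 1
        elif r.observed_imaging is ObservedImaging.CT:
            ct += 1
    if rad + ct == 0:
        raise ValueError("no records with observed radiography or CT imaging")
    return ModalityRatio(radiography_observed=rad, ct_observed=ct)


def actual_imaging(records: Sequence[PatientRecord], stratum: str = "all") -> ImagingProjection:
    """Observed disposition: no imaging / radiography / CT counts.

    MRI-only and other modalities are folded into the cleared column here
    only to keep the three-way partition exhaustive; they are excluded from
    all modality ratios.
    """
    rad = sum(1 for r in records if r.observed_imaging is ObservedImaging.RADIOGRAPHY)
    ct = sum(1 for r in records if r.observed_imaging is ObservedImaging.CT)
    return ImagingProjection(
        rule="actual",
        stratum=stratum,
        cleared_n=len(records) - rad - ct,
        radiography_n=rad,
        ct_n=ct,
    )


def project_pecarn(
    decisions: Sequence[tuple[str, RuleDecision]],
    n_total: int,
    stratum: str = "all",
) -> ImagingProjection:
    """Tier-based allocation for PECARN: CT tier -> CT, radiography tier -> radiography."""
    tiers = [d.tier for _, d in decisions]
    if len(tiers) != n_total:
        raise ValueError(f"expected {n_total} decisions, got {len(tiers)}")
    ct_n = sum(1 for t in tiers if t is Tier.CT)
    rad_n = sum(1 for t in tiers if t is Tier.RADIOGRAPHY)
    return ImagingProjection(
        rule=Rule.PECARN.value,
        stratum=stratum,
        cleared_n=n_total - ct_n - rad_n,
        radiography_n=rad_n,
        ct_n=ct_n,
    )


def project_binary_rule(
    decisions: Sequence[tuple[str, RuleDecision]],
    ratio: ModalityRatio,
    n_total: int,
    stratum: str = "all",
) -> ImagingProjection:
    """Ratio-based allocation for a binary rule (NEXUS or CCR).

    positives x ct_share rounded half-up gives CT; radiography is the
    remainder of the positives; everyone else is cleared.
    """
    if len(decisions) != n_total:
        raise ValueError(f"expected {n_total} decisions, got {len(decisions)}")
    rules = {d.rule for _, d in decisions}
    if len(rules) > 1:
        raise ValueError(f"mixed rules in decisions: {sorted(r.value for r in rules)}")
    positives = sum(1 for _, d in decisions if d.positive)
    ct_n = int(round_half_up(positives * ratio.ct_share, 0))
    rad_n = positives - ct_n
    rule = rules.pop().value if rules else "binary"
    return ImagingProjection(
        rule=rule,
        stratum=stratum,
        cleared_n=n_total - positives,
        radiography_n=rad_n,
        ct_n=ct_n,
        modality_ratio_source=ratio,
    )


def projection_report(
    records: Sequence[PatientRecord],
    rules: Iterable[Rule | str] = (Rule.PECARN, Rule.NEXUS, Rule.CCR),
    strata: Sequence[str] = ("all", "age_0_8", "age_9_17"),
    stratum_specific_ratio: bool = True,
    policy: RulePolicy = DEFAULT_POLICY,
) -> dict[tuple[str, str], ImagingProjection]:
    """Actual plus per-rule projected imaging for each requested stratum.

    By default each age stratum is projected with its own observed
    radiography:CT ratio, which reproduces the published age blocks; set
    ``stratum_specific_ratio=False`` to reuse the overall ratio everywhere.
    """
    young, old = stratify_by_age(records)
    subsets = {"all": list(records), "age_0_8": young.records, "age_9_17": old.records}
    overall_ratio = observed_modality_ratio(records)
    out: dict[tuple[str, str], ImagingProjection] = {}
    for label in strata:
        subset = subsets[label]
        ratio = (
            observed_modality_ratio(subset) if stratum_specific_ratio else overall_ratio
        )
        out[("actual", label)] = actual_imaging(subset, label)
        for rule in rules:
            rule = Rule(rule)
            decisions = classify_cohort(subset, rule, policy)
            if rule is Rule.PECARN:
                proj = project_pecarn(decisions, len(subset), label)
            else:
                proj = project_binary_rule(decisions, ratio, len(subset), label)
            out[(rule.value, label)] = proj
    return out


def projection_frame(report: Mapping[tuple[str, str], ImagingProjection]):
    """Flatten projections into a DataFrame mirroring the published layout."""
    import pandas as pd

    rows = []
    for (rule, stratum), p in report.items():
        rows.append(
            {
                "rule": rule,
                "stratum": stratum,
                "cleared_n": p.cleared_n,
                "cleared_pct": p.cleared_pct,
                "radiography_n": p.radiography_n,
                "radiography_pct": p.radiography_pct,
                "ct_n": p.ct_n,
                "ct_pct": p.ct_pct,
            }
        )
    return pd.DataFrame(rows)
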