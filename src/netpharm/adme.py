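"""ADME screening of formula components.

Candidate active components are kept when they jointly satisfy a
drug-likeness rule set: the Lipinski-style bounds on molecular weight,
hydrogen-bond donors/acceptors, rotatable bonds and logP, an oral
bioavailability floor (OB >= 30%), and — when the upstream predictor
supplied them — high gastrointestinal absorption, no high-level hERG
inhibition, and a negative carcinogenicity call.

The hydrogen-bond thresholds are applied inclusively (Hdon <= 5,
Hacc <= 10) by default: the canonical flavonol quercetin carries exactly
five donors and belongs in any sensible active set.  A strict mode with
open comparisons is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Literal

import pandas as pd
import yaml

from .io import ComponentRecord

__all__ = ["AdmeRuleSet", "ScreenVerdict", "evaluate_component", "screen_components"]

log = logging.getLogger(__name__)

UnknownPolicy = Literal["skip", "fail"]


@dataclass(frozen=True)
class AdmeRuleSet:
    """Thresholds for the component screen.

    Numeric comparators: mw strictly < ``mw_max``; hdon/hacc/rbn <= their
    maxima (or strictly < in ``strict_hbond`` mode); ``logp_min`` < logp <
    ``logp_max`` (both open); ob >= ``ob_min``.  Categorical rules may be
    disabled by setting the level to ``None``; an "unknown" property value
    is skipped or failed per ``unknown_policy``.
    """

    mw_max: float = 500.0
    hdon_max: int = 5
    hacc_max: int = 10
    rbn_max: int = 10
    logp_min: float = -2.0
    logp_max: float = 5.0
    ob_min: float = 30.0
    require_gi: str | None = "high"
    exclude_herg: str | None = "high"
    require_carcinogenicity: str | None = "negative"
    strict_hbond: bool = False
    unknown_policy: UnknownPolicy = "skip"

    def __post_init__(self) -> None:
        if not self.logp_min < self.logp_max:
            raise ValueError("logp_min must be < logp_max")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v != v:
                raise ValueError(f"{f.name} is not finite")

    @classmethod
    def from_yaml(cls, path) -> "AdmeRuleSet":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown rule key(s): {sorted(unknown)}")
        return cls(**raw)


RULE_NAMES = ("mw", "hdon", "hacc", "rbn", "logp", "ob", "gi", "herg", "carcinogenicity")


@dataclass(frozen=True)
class ScreenVerdict:
    """Per-rule booleans for one component; overall = AND of enabled rules."""

    component_id: str
    rules: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.rules.values())


def _categorical(value: str, ok: bool, policy: UnknownPolicy) -> bool:
    if value == "unknown":
        return policy == "skip"
    return ok


def evaluate_component(record: ComponentRecord, rules: AdmeRuleSet | None = None) -> ScreenVerdict:
    """Apply every enabled rule to one component and record each verdict."""
    rules = rules or AdmeRuleSet()
    hb_ok = (lambda v, m: v < m) if rules.strict_hbond else (lambda v, m: v <= m)
    verdicts: dict[str, bool] = {
        "mw": record.mw < rules.mw_max,
        "hdon": hb_ok(record.hdon, rules.hdon_max),
        "hacc": hb_ok(record.hacc, rules.hacc_max),
        "rbn": record.rbn <= rules.rbn_max,
        "logp": rules.logp_min < record.logp < rules.logp_max,
        "ob": record.ob >= rules.ob_min,
    }
    if rules.require_gi is not None:
        verdicts["gi"] = _categorical(
            record.gi_class, record.gi_class == rules.require_gi, rules.unknown_policy
        )
    if rules.exclude_herg is not None:
        verdicts["herg"] = _categorical(
            record.herg_class, record.herg_class != rules.exclude_herg, rules.unknown_policy
        )
    if rules.require_carcinogenicity is not None:
        verdicts["carcinogenicity"] = _categorical(
            record.carcinogenicity,
            record.carcinogenicity == rules.require_carcinogenicity,
            rules.unknown_policy,
        )
    return ScreenVerdict(component_id=record.component_id, rules=verdicts)


def screen_components(
    records: Iterable[ComponentRecord], rules: AdmeRuleSet | None = None
) -> tuple[list[ComponentRecord], pd.DataFrame]:
    """Screen a component table.

    Returns the kept records (input order preserved) and an auditable
    verdict table with one row per input component, per-rule boolean
    columns, and an overall ``passed`` flag.  The verdict table is a
    partition: |kept| + |failed| = |input|.
    """
    rules = rules or AdmeRuleSet()
    records = list(records)
    if not records:
        log.warning("screen_components called with zero records")
        return [], pd.DataFrame(columns=["component_id", "passed"])
    kept: list[ComponentRecord] = []
    rows = []
    for rec in records:
        verdict = evaluate_component(rec, rules)
        rows.append({"component_id": rec.component_id, **verdict.rules, "passed": verdict.passed})
        if verdict.passed:
            kept.append(rec)
    table = pd.DataFrame(rows)
    log.info("ADME screen: kept %d of %d components", len(kept), len(records))
    return kept, table
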