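"""Ligand-based virtual-screening cascade.

Stages run in order: predicted-activity cutoff (a compound with predicted
IC50 *more than* the threshold is excluded, so the boundary value passes),
Lipinski rule of five (classic one-violation allowance, configurable to
zero), then a transparent, configurable risk-rule engine standing in for
proprietary composite ADMET risk scores (sum of weights of triggered rules;
exclusion at score >= cutoff, default 10). Survivors are ranked by predicted
IC50 ascending; in multi-model mode the ranking key is the worst-case
(maximum) IC50 across models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

from .errors import MissingDescriptorError
from .qsar import LinearQSARModel, applicability_flag, predict

RO5_LIMITS = {"MW": 500.0, "logP": 5.0, "HBD": 5, "HBA": 10}


@dataclass
class RiskRule:
    """One named risk rule: predicate over a property mapping, plus weight.

    A rule that references a missing property counts as triggered
    (fail-closed), with the rule name annotated accordingly.
    """

    name: str
    predicate: Callable[[Mapping], bool]
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("rule weight must be >= 0")


def threshold_rule(name: str, prop: str, op: str, value: float, weight: float = 1.0) -> RiskRule:
    """Build a comparison rule (``prop op value``) — the serializable form."""
    ops = {
        ">": lambda a, b: a > b,
        ">=": lambda a, b: a >= b,
        "<": lambda a, b: a < b,
        "<=": lambda a, b: a <= b,
    }
    if op not in ops:
        raise ValueError(f"unknown operator {op!r}")
    cmp = ops[op]
    return RiskRule(name, lambda props: cmp(props[prop], value), weight)


def load_risk_rules(path) -> list[RiskRule]:
    """Load comparison rules from JSON:
    ``[{"name":..., "property":..., "op":..., "value":..., "weight":...}]``."""
    with open(path) as fh:
        entries = json.load(fh)
    return [
        threshold_rule(e["name"], e["property"], e["op"], e["value"], e.get("weight", 1.0))
        for e in entries
    ]


@dataclass
class ScreeningRecord:
    """Per-compound screening state and verdict."""

    compound_id: str
    smiles: Optional[str] = None
    descriptors: dict = field(default_factory=dict)
    properties: dict = field(default_factory=dict)  # rule-of-five inputs
    pred_log_ic50: dict[str, float] = field(default_factory=dict)  # per model
    pred_ic50_uM: dict[str, float] = field(default_factory=dict)
    ad_flag: dict[str, Union[int, str]] = field(default_factory=dict)
    ro5_violations: list[str] = field(default_factory=list)
    risk_score: float = 0.0
    risk_triggered: list[str] = field(default_factory=list)
    verdict: str = "pending"  # pass | fail | unevaluated | pending
    failing_stage: Optional[str] = None

    @property
    def worst_ic50(self) -> float:
        return max(self.pred_ic50_uM.values())


def activity_filter(
    records: Sequence[ScreeningRecord], threshold_uM: float, model_name: Optional[str] = None
) -> tuple[list[ScreeningRecord], list[ScreeningRecord], list[ScreeningRecord]]:
    """Partition records on the predicted-activity cutoff.

    A record passes iff its designated predicted IC50 is <= threshold
    (strictly-greater excluded). Records lacking the prediction go to an
    ``unevaluated`` bin, never silently passed.

    Returns (passed, failed, unevaluated).
    """
    if threshold_uM <= 0:
        raise ValueError("threshold must be > 0")
    passed, failed, unevaluated = [], [], []
    for rec in records:
        if model_name is not None:
            value = rec.pred_ic50_uM.get(model_name)
        else:
            value = max(rec.pred_ic50_uM.values()) if rec.pred_ic50_uM else None
        if value is None or not math.isfinite(value):
            rec.verdict = "unevaluated"
            rec.failing_stage = "activity"
            unevaluated.append(rec)
        elif value <= threshold_uM:
            passed.append(rec)
        else:
            rec.verdict = "fail"
            rec.failing_stage = "activity"
            failed.append(rec)
    return passed, failed, unevaluated


def rule_of_five(properties: Mapping, allowance: int = 1) -> tuple[bool, list[str]]:
    """Lipinski filter: violations among MW > 500, logP > 5, HBD > 5,
    HBA > 10 (limits inclusive); pass iff violations <= ``allowance``.

    A missing/None property fails closed with an ``unevaluable`` violation.
    """
    violations = []
    for prop, limit in RO5_LIMITS.items():
        value = properties.get(prop) if hasattr(properties, "get") else properties[prop]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            violations.append(f"{prop} unevaluable")
        elif value > limit:
            violations.append(f"{prop} > {limit:g}")
    ok = len(violations) <= allowance and not any("unevaluable" in v for v in violations)
    return ok, violations


def risk_rules(
    properties: Mapping, rule_set: Sequence[RiskRule]
) -> tuple[float, list[str]]:
    """Evaluate a risk rule set; returns (score, triggered rule names).

    Score is the sum of weights of triggered rules. A rule whose predicate
    raises on a missing property is counted as triggered (fail-closed).
    """
    score = 0.0
    triggered = []
    for rule in rule_set:
        try:
            hit = bool(rule.predicate(properties))
        except (KeyError, TypeError):
            hit = True
            triggered.append(f"{rule.name} (missing property; fail-closed)")
            score += rule.weight
            continue
        if hit:
            triggered.append(rule.name)
            score += rule.weight
    return score, triggered


@dataclass
class ScreenConfig:
    threshold_uM: float = 20.0
    model_name: Optional[str] = None  # rank/filter on this model; None = worst case
    ro5_enabled: bool = True
    ro5_allowance: int = 1
    risk_rule_set: list[RiskRule] = field(default_factory=list)
    risk_cutoff: float = 10.0


@dataclass
class ScreeningReport:
    records: list[ScreeningRecord]
    passers: list[ScreeningRecord]
    attrition: dict[str, int]
    config: ScreenConfig

    def ranked_ids(self) -> list[str]:
        return [r.compound_id for r in self.passers]


def _predict_records(records: Sequence[ScreeningRecord], models: Sequence[LinearQSARModel]):
    for rec in records:
        for model in models:
            try:
                p = predict(model, rec.descriptors)
            except MissingDescriptorError:
                continue
            rec.pred_log_ic50[model.name] = p.log_ic50
            rec.pred_ic50_uM[model.name] = p.ic50_uM
            rec.ad_flag[model.name] = applicability_flag(model, rec.descriptors)


def screen_library(
    library: Sequence[ScreeningRecord],
    models: Sequence[LinearQSARModel],
    config: Optional[ScreenConfig] = None,
) -> ScreeningReport:
    """Run the full cascade over a compound library.

    Stage order: activity -> rule of five -> risk rules. Deterministic for
    fixed inputs; per-stage attrition counts are reported. Survivors are
    ranked by predicted IC50 ascending (ties by compound id).
    """
    config = config or ScreenConfig()
    if not models:
        raise ValueError("at least one model is required")
    records = list(library)
    if not records:
        return ScreeningReport([], [], {"input": 0}, config)

    _predict_records(records, models)

    attrition = {"input": len(records)}
    current, failed_act, unevaluated = activity_filter(
        records, config.threshold_uM, config.model_name
    )
    attrition["activity"] = len(failed_act)
    attrition["unevaluated"] = len(unevaluated)

    if config.ro5_enabled:
        survivors = []
        n_fail = 0
        for rec in current:
            props = dict(rec.properties)
            if not props and rec.smiles is not None:
                from .descriptors import rule_of_five_properties
                from .molgraph import parse_smiles

                props = rule_of_five_properties(parse_smiles(rec.smiles))
                rec.properties = props
            ok, violations = rule_of_five(props, config.ro5_allowance)
            rec.ro5_violations = violations
            if ok:
                survivors.append(rec)
            else:
                rec.verdict = "fail"
                rec.failing_stage = "rule_of_five"
                n_fail += 1
        attrition["rule_of_five"] = n_fail
        current = survivors
    else:
        attrition["rule_of_five"] = 0

    survivors = []
    n_fail = 0
    for rec in current:
        score, triggered = risk_rules(rec.properties, config.risk_rule_set)
        rec.risk_score = score
        rec.risk_triggered = triggered
        if score >= config.risk_cutoff and config.risk_rule_set:
            rec.verdict = "fail"
            rec.failing_stage = "risk_rules"
            n_fail += 1
        else:
            survivors.append(rec)
    attrition["risk_rules"] = n_fail

    def rank_key(rec: ScreeningRecord):
        if config.model_name is not None:
            return (rec.pred_ic50_uM[config.model_name], str(rec.compound_id))
        return (rec.worst_ic50, str(rec.compound_id))

    survivors.sort(key=rank_key)
    for rec in survivors:
        rec.verdict = "pass"
        rec.failing_stage = None
    attrition["passed"] = len(survivors)
    return ScreeningReport(records, survivors, attrition, config)


def report_frame(report: ScreeningReport):
    """Flatten a screening report to a DataFrame (one row per compound)."""
    import pandas as pd

    rows = []
    for rec in report.records:
        row = {
            "compound_id": rec.compound_id,
            "smiles": rec.smiles,
            "verdict": rec.verdict,
            "failing_stage": rec.failing_stage or "",
            "ro5_violations": ";".join(rec.ro5_violations),
            "risk_score": rec.risk_score,
            "risk_triggered": ";".join(rec.risk_triggered),
        }
        for name, v in rec.pred_log_ic50.items():
            row[f"pred_log_ic50[{name}]"] = v
            row[f"pred_ic50_uM[{name}]"] = rec.pred_ic50_uM[name]
            row[f"ad_flag[{name}]"] = rec.ad_flag.get(name, "unavailable")
        rows.append(row)
    return pd.DataFrame(rows)
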