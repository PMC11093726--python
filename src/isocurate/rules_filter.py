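"""JSON-rule based isoform/artifact filtering.

A rules document maps a structural category (or ``"rest"``, covering every
category not explicitly keyed) to a list of *rules*; each rule is a set of
*requisites* on classification-table columns. Requisites within a rule are
ANDed; rules for the same category are ORed. A transcript passes when at
least one rule for its category is fully satisfied.

Numeric requisites are either a closed interval ``[lo, hi]`` or a bare
lower bound; categorical requisites list the accepted levels (booleans are
matched as the levels TRUE/FALSE). Missing values fail every requisite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .classify import CATEGORIES

REST = "rest"


@dataclass(frozen=True)
class Requisite:
    column: str
    lo: Optional[float] = None
    hi: Optional[float] = None
    levels: Optional[frozenset[str]] = None

    def is_numeric(self) -> bool:
        return self.levels is None

    def satisfied(self, value) -> bool:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        if self.is_numeric():
            try:
                v = float(value)
            except (TypeError, ValueError):
                return False
            if math.isnan(v):
                return False
            if self.lo is not None and v < self.lo:
                return False
            if self.hi is not None and v > self.hi:
                return False
            return True
        return _level(value) in self.levels

    def describe(self) -> str:
        if self.is_numeric():
            if self.hi is None:
                return f"{self.column}>={self.lo}"
            return f"{self.column} in [{self.lo},{self.hi}]"
        return f"{self.column} in {{{','.join(sorted(self.levels))}}}"


def _level(value) -> str:
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    return str(value)


Rule = tuple  # tuple of Requisite


@dataclass
class RulesSpec:
    rules: dict[str, list[Rule]] = field(default_factory=dict)

    def rules_for(self, category: str) -> list[Rule]:
        if category in self.rules:
            return self.rules[category]
        return self.rules.get(REST, [])


@dataclass
class FilterDecision:
    transcript_id: str
    verdict: str                      # isoform | artifact
    reasons: list[str] = field(default_factory=list)
    probability: Optional[float] = None

    @property
    def is_isoform(self) -> bool:
        return self.verdict == "isoform"


class RulesError(ValueError):
    pass


def parse_rules(doc: Union[str, dict], schema: Sequence[str],
                numeric_columns: Optional[set[str]] = None) -> RulesSpec:
    """Parse and validate a rules document against a table schema.

    ``doc`` is a JSON string or an already-decoded mapping. ``schema`` lists
    the classification-table columns rules may reference;
    ``numeric_columns`` restricts interval constraints to numeric columns
    when provided.
    """
    if isinstance(doc, str):
        doc = json.loads(doc)
    if not isinstance(doc, dict):
        raise RulesError("rules document must be a JSON object")
    schema_set = set(schema)
    spec = RulesSpec()
    for category, rules in doc.items():
        if category not in CATEGORIES and category != REST:
            raise RulesError(f"unknown structural category {category!r}")
        if not isinstance(rules, list) or not rules:
            raise RulesError(f"{category}: expected a non-empty list of rules")
        parsed = []
        for rule in rules:
            if not isinstance(rule, dict) or not rule:
                raise RulesError(f"{category}: each rule must be a non-empty "
                                 "object of requisites")
            reqs = []
            for column, constraint in rule.items():
                if column not in schema_set:
                    raise RulesError(f"{category}: unknown column {column!r}")
                reqs.append(_parse_requisite(column, constraint,
                                             numeric_columns))
            parsed.append(tuple(reqs))
        spec.rules[category] = parsed
    return spec


def _parse_requisite(column: str, constraint,
                     numeric_columns: Optional[set[str]]) -> Requisite:
    def check_numeric():
        if numeric_columns is not None and column not in numeric_columns:
            raise RulesError(f"numeric constraint on non-numeric column "
                             f"{column!r}")

    if isinstance(constraint, bool):
        return Requisite(column, levels=frozenset([_level(constraint)]))
    if isinstance(constraint, (int, float)):
        check_numeric()
        return Requisite(column, lo=float(constraint))
    if isinstance(constraint, str):
        return Requisite(column, levels=frozenset([constraint]))
    if isinstance(constraint, list):
        if len(constraint) == 2 and all(
                isinstance(x, (int, float)) and not isinstance(x, bool)
                for x in constraint):
            check_numeric()
            lo, hi = float(constraint[0]), float(constraint[1])
            if lo > hi:
                raise RulesError(f"{column}: interval lower bound exceeds "
                                 "upper bound")
            return Requisite(column, lo=lo, hi=hi)
        if constraint and all(isinstance(x, (str, bool)) for x in constraint):
            return Requisite(column,
                             levels=frozenset(_level(x) for x in constraint))
    raise RulesError(f"{column}: unsupported constraint {constraint!r}")


def apply_rules(records: pd.DataFrame, spec: RulesSpec) -> list[FilterDecision]:
    """Evaluate the rules document over a classification table.

    Every transcript gets a verdict; artifacts carry the failed requisites
    of each unsatisfied rule as reasons.
    """
    decisions = []
    for _, row in records.iterrows():
        rules = spec.rules_for(row["structural_category"])
        if not rules:
            decisions.append(FilterDecision(row["isoform"], "isoform"))
            continue
        failures: list[str] = []
        passed = False
        for rule in rules:
            failed = [r.describe() for r in rule
                      if not r.satisfied(row.get(r.column))]
            if not failed:
                passed = True
                break
            failures.extend(failed)
        if passed:
            decisions.append(FilterDecision(row["isoform"], "isoform"))
        else:
            # deduplicate, preserving order
            seen = dict.fromkeys(failures)
            decisions.append(FilterDecision(row["isoform"], "artifact",
                                            reasons=list(seen)))
    return decisions


def default_rules(drop_mono_exon: bool = False) -> RulesSpec:
    """The default curation rules.

    FSM transcripts are removed solely on intrapriming. All other
    categories must be negative for intrapriming and RT switching and have
    every junction supported by at least three short reads, or
    alternatively have only canonical junctions.
    """
    false = frozenset(["FALSE"])
    true = frozenset(["TRUE"])
    fsm_rule = [Requisite("intrapriming", levels=false)]
    base = [Requisite("intrapriming", levels=false),
            Requisite("RTS_stage", levels=false)]
    rest_rules = [tuple(base + [Requisite("min_cov", lo=3.0)]),
                  tuple(base + [Requisite("all_canonical", levels=true)])]
    if drop_mono_exon:
        multi = Requisite("exons", lo=2.0)
        fsm_rule = fsm_rule + [multi]
        rest_rules = [tuple(list(r) + [multi]) for r in rest_rules]
    return RulesSpec(rules={"FSM": [tuple(fsm_rule)], REST: rest_rules})


def decisions_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame({
        "isoform": [d.transcript_id for d in decisions],
        "filter_result": [d.verdict for d in decisions],
        "reasons": [";".join(d.reasons) if d.reasons else
                    ("ml_probability" if d.probability is not None and
                     d.verdict == "artifact" else "") for d in decisions],
        "POS_MLprob": [d.probability for d in decisions],
    })
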