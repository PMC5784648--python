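"""Detection of potentially missing comorbidities (steps 2 and 3).

Step 2 compares, within each hospital stay, the ICD-10 billing codes with
the indications of every prescribed drug: a prescription none of whose
indications appears among the stay's billing codes is a clue for a missing
diagnosis, and the drug's comorbidity-linked indications (minus codes
already billed) are emitted as a suggestion for expert review.

Step 3 fuses narrow-indication drug prescriptions with laboratory results
through declarative threshold rules — the worked instance is sodium
polystyrene sulfonate (SPS, prescribed only for hyperkalemia) combined
with plasma potassium > 5.0 mmol/L, targeting ICD-10 E87.5.

Nothing is ever written back to the billing record: suggestions are for
human review only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from .ehr import Cohort, Stay
from .errors import ConfigError
from .icd10 import normalize_code
from .kb import EnrichedKnowledgeBase
from .rounding import pct, round1

__all__ = [
    "MatchPolicy",
    "PrescriptionMatch",
    "Suggestion",
    "LabRule",
    "load_lab_rules",
    "filter_cohort",
    "match_stay",
    "detected_code_fraction",
    "suggest_missing",
    "apply_lab_rules",
    "run_pipeline",
]


class MatchPolicy(str, Enum):
    """Granularity for comparing an indication with a billing code.

    ``exact`` requires normalized equality (conservative default);
    ``category3`` matches on the three-character ICD-10 category, useful as
    a sensitivity analysis since coders and drug databases may code at
    different depths.
    """

    EXACT = "exact"
    CATEGORY3 = "category3"

    def codes_equal(self, a: str, b: str) -> bool:
        if self is MatchPolicy.EXACT:
            return a == b
        return a[:3] == b[:3]


@dataclass(frozen=True)
class PrescriptionMatch:
    """Outcome of matching one prescribed drug against a stay's codes."""

    stay_id: str
    cud: str
    matched: bool
    matching_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        assert self.matched == bool(self.matching_codes)


@dataclass(frozen=True)
class Suggestion:
    """A candidate missing diagnosis emitted for expert review."""

    stay_id: str
    cud: str
    candidate_codes: frozenset[str]
    source: str  # drug_only | drug_plus_lab | lab_only
    evidence: str = ""


@dataclass(frozen=True)
class LabRule:
    """Declarative threshold rule linking labs (and optionally a trigger
    drug set) to one target ICD-10 code.

    An empty ``trigger_cuds`` makes the rule lab-only: any stay with a
    qualifying result and no target code is flagged.
    """

    rule_id: str
    trigger_cuds: frozenset[str]
    analyte: str
    comparator: str  # gt | ge | lt | le
    threshold: float
    unit: str
    target_code: str

    def __post_init__(self) -> None:
        if self.comparator not in ("gt", "ge", "lt", "le"):
            raise ConfigError(f"rule {self.rule_id}: unknown comparator {self.comparator!r}")
        object.__setattr__(self, "target_code", normalize_code(self.target_code))
        object.__setattr__(self, "trigger_cuds", frozenset(self.trigger_cuds))

    def qualifies(self, value: float) -> bool:
        return {
            "gt": value > self.threshold,
            "ge": value >= self.threshold,
            "lt": value < self.threshold,
            "le": value <= self.threshold,
        }[self.comparator]


#: The worked rule pair: hyperkalemia (E87.5) from potassium > 5.0 mmol/L,
#: with and without an SPS prescription trigger.
def hyperkalemia_rules(sps_cud: str = "SPS00") -> list[LabRule]:
    common = dict(analyte="potassium", comparator="gt", threshold=5.0, unit="mmol/L", target_code="E875")
    return [
        LabRule(rule_id="hyperkalemia_sps", trigger_cuds=frozenset({sps_cud}), **common),
        LabRule(rule_id="hyperkalemia_lab_only", trigger_cuds=frozenset(), **common),
    ]


def load_lab_rules(path, canonical_units: dict[str, str] | None = None) -> list[LabRule]:
    """Load rules from a JSON list and check units against the canonical map."""
    with open(path) as fh:
        raw = json.load(fh)
    rules = [
        LabRule(
            rule_id=r["rule_id"],
            trigger_cuds=frozenset(r.get("trigger_cuds", [])),
            analyte=r["analyte"],
            comparator=r["comparator"],
            threshold=float(r["threshold"]),
            unit=r["unit"],
            target_code=r["target_code"],
        )
        for r in raw
    ]
    validate_rule_units(rules, canonical_units)
    return rules


def validate_rule_units(rules, canonical_units: dict[str, str] | None) -> None:
    from .ehr import DEFAULT_CANONICAL_UNITS

    units = DEFAULT_CANONICAL_UNITS if canonical_units is None else canonical_units
    for rule in rules:
        canon = units.get(rule.analyte)
        if canon is None:
            raise ConfigError(f"rule {rule.rule_id}: no canonical unit declared for analyte {rule.analyte!r}")
        if rule.unit != canon:
            raise ConfigError(
                f"rule {rule.rule_id}: threshold unit {rule.unit!r} != canonical {canon!r} for {rule.analyte!r}"
            )


# ---------------------------------------------------------------------------
# cohort inclusion filter

INCLUSION_REASONS = ("no_rx", "no_kept_drug", "no_indication_drug")


def filter_cohort(cohort: Cohort, ekb: EnrichedKnowledgeBase) -> tuple[Cohort, dict[str, int]]:
    """Keep stays usable by the detector; count removals per reason.

    A stay is included iff it has at least one prescription, at least one
    prescription of a non-excluded drug, and at least one of those kept
    drugs carries a non-empty indication set. Reasons are assessed in that
    order, so each removed stay is counted once under the first failure.
    """
    included: list[Stay] = []
    report = {r: 0 for r in INCLUSION_REASONS}
    for stay in cohort:
        if not stay.prescriptions:
            report["no_rx"] += 1
            continue
        kept = [cud for cud in stay.prescribed_cuds if ekb.is_kept(cud)]
        if not kept:
            report["no_kept_drug"] += 1
            continue
        if not any(ekb.indications(cud) for cud in kept):
            report["no_indication_drug"] += 1
            continue
        included.append(stay)
    return Cohort(stays=tuple(included), metadata=dict(cohort.metadata)), report


# ---------------------------------------------------------------------------
# step 2: matching and suggestions

def match_stay(
    stay: Stay, ekb: EnrichedKnowledgeBase, policy: MatchPolicy = MatchPolicy.EXACT
) -> list[PrescriptionMatch]:
    """Match each prescribed kept drug against the stay's billing codes.

    Repeat prescriptions of one drug collapse to a single match record;
    drugs absent from the knowledge base are skipped (they carry no
    indication information), as are excluded drugs.
    """
    out: list[PrescriptionMatch] = []
    for cud in sorted(stay.prescribed_cuds):
        if not ekb.is_kept(cud):
            continue
        inds = ekb.indications(cud)
        hits = frozenset(b for b in stay.billing_codes if any(policy.codes_equal(b, i) for i in inds))
        out.append(PrescriptionMatch(stay_id=stay.stay_id, cud=cud, matched=bool(hits), matching_codes=hits))
    return out


def detected_code_fraction(cohort: Cohort, matches: list[PrescriptionMatch]) -> float:
    """Share of billing-code instances matched by >=1 prescribed drug.

    Counts distinct (stay, code) pairs over the included cohort; returns a
    percentage rounded half-up to one decimal.
    """
    total = sum(len(s.billing_codes) for s in cohort)
    if total == 0:
        raise ConfigError("cohort has no billing codes")
    hit: set[tuple[str, str]] = set()
    for m in matches:
        for code in m.matching_codes:
            hit.add((m.stay_id, code))
    return round1(pct(len(hit), total))


def suggest_missing(
    stay: Stay, matches: list[PrescriptionMatch], ekb: EnrichedKnowledgeBase
) -> list[Suggestion]:
    """Emit drug-based suggestions for the stay's unmatched prescriptions.

    Each unmatched drug with at least one comorbidity-linked indication
    yields one suggestion whose candidates are those indications minus the
    codes already billed; drugs whose comorbidity intersection is empty are
    silent (their indications cannot name a major comorbid condition).
    """
    out: list[Suggestion] = []
    for m in matches:
        if m.matched:
            continue
        candidates = ekb.comorbid_indications.get(m.cud, frozenset()) - stay.billing_codes
        if candidates:
            out.append(
                Suggestion(stay_id=stay.stay_id, cud=m.cud, candidate_codes=candidates, source="drug_only")
            )
    return out


# ---------------------------------------------------------------------------
# step 3: drug + lab fusion

def apply_lab_rules(stay: Stay, rules: list[LabRule]) -> list[Suggestion]:
    """Apply threshold rules to one stay's laboratory results.

    A triggered rule requires (i) for non-empty trigger sets, at least one
    prescription of a trigger drug; (ii) the target code absent from the
    billing codes; (iii) at least one result of the rule's analyte whose
    value satisfies the comparator. The reported evidence is the extremal
    qualifying value (max for gt/ge, min for lt/le). Only results observed
    within [admit, discharge] are considered.
    """
    out: list[Suggestion] = []
    for rule in rules:
        if rule.trigger_cuds and not (stay.prescribed_cuds & rule.trigger_cuds):
            continue
        if rule.target_code in stay.billing_codes:
            continue
        values = [
            lab.value
            for lab in stay.labs
            if lab.analyte == rule.analyte and stay.admit <= lab.observed.date() <= stay.discharge
        ]
        qualifying = [v for v in values if rule.qualifies(v)]
        if not qualifying:
            continue
        extremal = max(qualifying) if rule.comparator in ("gt", "ge") else min(qualifying)
        out.append(
            Suggestion(
                stay_id=stay.stay_id,
                cud="|".join(sorted(stay.prescribed_cuds & rule.trigger_cuds)),
                candidate_codes=frozenset({rule.target_code}),
                source="drug_plus_lab" if rule.trigger_cuds else "lab_only",
                evidence=f"{rule.rule_id}: {rule.analyte}={extremal:g} {rule.unit}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PipelineResult:
    included: Cohort
    exclusion_report: dict[str, int]
    matches: list[PrescriptionMatch]
    suggestions: list[Suggestion]
    summary: dict = field(default_factory=dict)


def _lab_rule_summary(cohort: Cohort, rules: list[LabRule], suggestions: list[Suggestion]) -> dict:
    per_rule = {}
    flagged_by_rule: dict[str, set[str]] = {r.rule_id: set() for r in rules}
    for s in suggestions:
        if s.source in ("drug_plus_lab", "lab_only"):
            rid = s.evidence.split(":", 1)[0]
            flagged_by_rule.setdefault(rid, set()).add(s.stay_id)
    for rule in rules:
        if rule.trigger_cuds:
            eligible = [
                s for s in cohort
                if (s.prescribed_cuds & rule.trigger_cuds) and rule.target_code not in s.billing_codes
            ]
            n_trigger = sum(1 for s in cohort if s.prescribed_cuds & rule.trigger_cuds)
        else:
            eligible = [s for s in cohort if any(l.analyte == rule.analyte for l in s.labs)]
            n_trigger = len(eligible)
        n_elig = len(eligible)
        n_flag = len(flagged_by_rule.get(rule.rule_id, set()))
        per_rule[rule.rule_id] = {
            "n_trigger_stays": n_trigger,
            "n_eligible": n_elig,
            "n_flagged": n_flag,
            "pct_flagged": round1(pct(n_flag, n_elig)) if n_elig else None,
        }
    return per_rule


def run_pipeline(
    cohort: Cohort,
    ekb: EnrichedKnowledgeBase,
    policy: MatchPolicy = MatchPolicy.EXACT,
    rules: list[LabRule] | None = None,
) -> PipelineResult:
    """Filter → match → suggest → lab rules, with a summary of the headline
    fractions. Fully deterministic given its inputs."""
    rules = rules or []
    included, report = filter_cohort(cohort, ekb)
    matches: list[PrescriptionMatch] = []
    suggestions: list[Suggestion] = []
    suggested_stays: set[str] = set()
    for stay in included:
        m = match_stay(stay, ekb, policy)
        matches.extend(m)
        drug_sugg = suggest_missing(stay, m, ekb)
        if drug_sugg:
            suggested_stays.add(stay.stay_id)
        suggestions.extend(drug_sugg)
        suggestions.extend(apply_lab_rules(stay, rules))

    n_inc = len(included)
    total_codes = sum(len(s.billing_codes) for s in included)
    summary = {
        "n_stays_input": len(cohort),
        "n_stays_included": n_inc,
        "exclusions": report,
        "n_suggested_stays": len(suggested_stays),
        "suggestion_rate_pct": round1(pct(len(suggested_stays), n_inc)) if n_inc else None,
        "n_billing_code_instances": total_codes,
        "detected_code_fraction_pct": detected_code_fraction(included, matches) if total_codes else None,
        "lab_rules": _lab_rule_summary(included, rules, suggestions),
    }
    return PipelineResult(
        included=included,
        exclusion_report=report,
        matches=matches,
        suggestions=suggestions,
        summary=summary,
    )
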