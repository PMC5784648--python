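"""Detection pipeline: filtering, matching, suggestions, lab rules.

The matching/suggestion logic is checked against a brute-force triple-loop
reference (stay x prescription x billing code) on random cohorts, plus the
structural invariants: suggestions never duplicate billed codes, adding a
billing code never creates suggestions, and exact matches are a subset of
category-level matches.
"""

import random
from datetime import date, datetime

import pytest

from comorbex.detect import (
    LabRule,
    MatchPolicy,
    apply_lab_rules,
    detected_code_fraction,
    filter_cohort,
    hyperkalemia_rules,
    match_stay,
    run_pipeline,
    suggest_missing,
)
from comorbex.ehr import Cohort, LabResult, Prescription, Stay
from comorbex.errors import ConfigError
from comorbex.kb import ComorbidityList, DrugRecord, build_enriched_kb

ADMIT, DISCHARGE = date(2015, 1, 1), date(2015, 1, 10)


def _stay(sid, codes=(), cuds=(), labs=()):
    return Stay(
        stay_id=sid, patient_id=f"P{sid}", admit=ADMIT, discharge=DISCHARGE,
        billing_codes=frozenset(codes),
        prescriptions=tuple(Prescription(cud=c, start=ADMIT) for c in cuds),
        labs=tuple(labs),
    )


def _ekb(drug_inds: dict, cmb_codes=("E875",), broad_cuds=()):
    drugs = [DrugRecord(cud=c, atc="C09AA", label=c, indications=frozenset(inds))
             for c, inds in drug_inds.items()]
    drugs += [DrugRecord(cud=c, atc="C09AA", label=c,
                         indications=frozenset(f"A{i:03d}" for i in range(25))) for c in broad_cuds]
    return build_enriched_kb(drugs, ComorbidityList(codes=frozenset(cmb_codes)))


class TestFilterCohort:
    # enrich without exclusions so a kept drug may carry no indications,
    # exercising the third inclusion reason; DBROAD is simply absent
    from comorbex.kb import enrich as _enrich
    ekb = _enrich(
        [DrugRecord(cud="D1", atc="C09AA", label="D1", indications=frozenset({"E875"})),
         DrugRecord(cud="D0", atc="C09AA", label="D0")],
        ComorbidityList(codes=frozenset({"E875"})),
    )

    def test_reasons_in_order(self):
        cohort = Cohort(stays=(
            _stay("no_rx"),
            _stay("broad_only", cuds=["DBROAD"]),
            _stay("no_ind", cuds=["D0"]),
            _stay("ok", cuds=["D1"]),
        ))
        included, report = filter_cohort(cohort, self.ekb)
        assert [s.stay_id for s in included] == ["ok"]
        assert report == {"no_rx": 1, "no_kept_drug": 1, "no_indication_drug": 1}


class TestMatchStay:
    def test_exact_identity_and_miss(self):
        ekb = _ekb({"D1": {"E875"}})
        hit = match_stay(_stay("S", codes={"E875"}, cuds=["D1"]), ekb)[0]
        miss = match_stay(_stay("S", codes={"I10"}, cuds=["D1"]), ekb)[0]
        assert hit.matched and hit.matching_codes == {"E875"}
        assert not miss.matched and miss.matching_codes == frozenset()

    def test_category3_prefix_matching(self):
        ekb = _ekb({"D1": {"I110"}})
        stay = _stay("S", codes={"I119"}, cuds=["D1"])
        assert not match_stay(stay, ekb, MatchPolicy.EXACT)[0].matched
        assert match_stay(stay, ekb, MatchPolicy.CATEGORY3)[0].matched

    def test_category3_agrees_with_bruteforce_prefix_rule(self):
        # all pairs of codes of length <= 4 over a tiny alphabet
        pool = [f"I{a}{b}{c}".rstrip("_").replace("_", "")
                for a in "01" for b in "019" for c in ["", "0", "9"]]
        for a in pool:
            for b in pool:
                ekb = _ekb({"D1": {a}})
                got = match_stay(_stay("S", codes={b}, cuds=["D1"]), ekb, MatchPolicy.CATEGORY3)[0].matched
                assert got == (a[:3] == b[:3])

    def test_unknown_cud_skipped(self):
        ekb = _ekb({"D1": {"E875"}})
        matches = match_stay(_stay("S", codes={"E875"}, cuds=["D1", "UNKNOWN"]), ekb)
        assert [m.cud for m in matches] == ["D1"]

    def test_repeat_prescriptions_collapse(self):
        ekb = _ekb({"D1": {"E875"}})
        assert len(match_stay(_stay("S", codes={"E875"}, cuds=["D1", "D1", "D1"]), ekb)) == 1


class TestSuggestMissing:
    def test_unmatched_comorbid_drug_suggests(self):
        ekb = _ekb({"D1": {"E875", "Z000"}})
        stay = _stay("S", codes=set(), cuds=["D1"])
        sugg = suggest_missing(stay, match_stay(stay, ekb), ekb)
        assert len(sugg) == 1
        assert sugg[0].candidate_codes == {"E875"}  # only the comorbidity-linked part
        assert sugg[0].source == "drug_only"

    def test_no_comorbid_indication_is_silent(self):
        ekb = _ekb({"D1": {"Z000"}})
        stay = _stay("S", codes={"I10"}, cuds=["D1"])
        assert suggest_missing(stay, match_stay(stay, ekb), ekb) == []

    def test_billed_codes_subtracted(self):
        ekb = _ekb({"D1": {"E875", "N189"}}, cmb_codes=("E875", "N189"))
        stay = _stay("S", codes={"E875x"}, cuds=["D1"])  # E875X bills a sibling, not the code
        sugg = suggest_missing(stay, match_stay(stay, ekb), ekb)
        assert sugg[0].candidate_codes == {"E875", "N189"}


class TestLabRules:
    rules = hyperkalemia_rules("SPS00")

    def _k(self, v, when=datetime(2015, 1, 2, 8, 0)):
        return LabResult(analyte="potassium", value=v, unit="mmol/L", observed=when)

    def test_combined_rule_fires(self):
        stay = _stay("S", cuds=["SPS00"], labs=[self._k(5.6)])
        out = apply_lab_rules(stay, self.rules)
        srcs = {s.source for s in out}
        assert srcs == {"drug_plus_lab", "lab_only"}
        assert all(s.candidate_codes == {"E875"} for s in out)

    def test_threshold_is_strict(self):
        stay = _stay("S", cuds=["SPS00"], labs=[self._k(5.0)])
        assert apply_lab_rules(stay, self.rules) == []

    def test_lab_only_without_trigger_drug(self):
        stay = _stay("S", cuds=["OTHER"], labs=[self._k(5.6)])
        out = apply_lab_rules(stay, self.rules)
        assert [s.source for s in out] == ["lab_only"]

    def test_already_coded_stay_is_silent(self):
        stay = _stay("S", codes={"E875"}, cuds=["SPS00"], labs=[self._k(6.1)])
        assert apply_lab_rules(stay, self.rules) == []

    def test_evidence_reports_extremal_value(self):
        stay = _stay("S", cuds=["SPS00"], labs=[self._k(5.2), self._k(6.3), self._k(4.1)])
        out = apply_lab_rules(stay, self.rules)
        assert all("6.3" in s.evidence for s in out)

    def test_out_of_stay_lab_ignored(self):
        stay = _stay("S", cuds=["SPS00"], labs=[self._k(6.0, datetime(2015, 2, 1))])
        assert apply_lab_rules(stay, self.rules) == []

    def test_combined_implies_lab_only(self):
        # every drug_plus_lab flag would also be raised by the lab-only rule
        rng = random.Random(3)
        for _ in range(50):
            stay = _stay(
                "S",
                codes={"E875"} if rng.random() < 0.3 else set(),
                cuds=["SPS00"] if rng.random() < 0.5 else ["OTHER"],
                labs=[self._k(round(rng.uniform(3.0, 7.0), 1))],
            )
            out = apply_lab_rules(stay, self.rules)
            srcs = {s.source for s in out}
            if "drug_plus_lab" in srcs:
                assert "lab_only" in srcs

    def test_unknown_analyte_unit_is_config_error(self):
        with pytest.raises(ConfigError):
            from comorbex.detect import validate_rule_units
            validate_rule_units(
                [LabRule(rule_id="r", trigger_cuds=frozenset(), analyte="troponin",
                         comparator="gt", threshold=14, unit="ng/L", target_code="I21.9")],
                None,
            )


def test_detected_code_fraction_all_matched():
    ekb = _ekb({"D1": {"E875"}})
    cohort = Cohort(stays=(_stay("S1", codes={"E875"}, cuds=["D1"]),))
    matches = match_stay(cohort.stays[0], ekb)
    assert detected_code_fraction(cohort, matches) == 100.0


def test_detected_code_fraction_zero_codes_is_error():
    cohort = Cohort(stays=(_stay("S1", cuds=["D1"]),))
    with pytest.raises(ConfigError):
        detected_code_fraction(cohort, [])


def test_empty_cohort_summary_has_flagged_denominators():
    ekb = _ekb({"D1": {"E875"}})
    result = run_pipeline(Cohort(stays=(_stay("S1"),)), ekb)
    assert result.summary["n_stays_included"] == 0
    assert result.summary["suggestion_rate_pct"] is None
    assert result.summary["detected_code_fraction_pct"] is None


# ---------------------------------------------------------------------------
# randomized properties against a brute-force reference

CODE_POOL = [f"{c}{i:02d}{s}" for c in "EIK" for i in range(8) for s in ("", "0")]


def _random_world(rng):
    drug_inds = {
        f"D{j}": {rng.choice(CODE_POOL) for _ in range(rng.randint(0, 4))}
        for j in range(rng.randint(1, 8))
    }
    cmb = {c for c in CODE_POOL if rng.random() < 0.4} or {CODE_POOL[0]}
    ekb = _ekb(drug_inds, cmb_codes=tuple(cmb))
    stays = tuple(
        _stay(
            f"S{i}",
            codes={rng.choice(CODE_POOL) for _ in range(rng.randint(0, 5))},
            cuds=[rng.choice(list(drug_inds)) for _ in range(rng.randint(0, 4))],
        )
        for i in range(rng.randint(1, 50))
    )
    return Cohort(stays=stays), ekb, drug_inds, cmb


def _bruteforce(cohort, ekb, drug_inds, cmb, policy):
    """Triple loop over stay x prescription x billing code."""
    matches, suggestions = set(), set()
    for stay in cohort:
        if not stay.prescriptions:
            continue
        kept = sorted({p.cud for p in stay.prescriptions if p.cud in ekb.drugs})
        if not any(drug_inds[c] for c in kept):
            continue
        for cud in kept:
            hit = set()
            for b in stay.billing_codes:
                for ind in drug_inds[cud]:
                    if (b == ind) if policy is MatchPolicy.EXACT else (b[:3] == ind[:3]):
                        hit.add(b)
            matches.add((stay.stay_id, cud, frozenset(hit)))
            if not hit:
                cand = (drug_inds[cud] & cmb) - stay.billing_codes
                if cand:
                    suggestions.add((stay.stay_id, cud, frozenset(cand)))
    return matches, suggestions


@pytest.mark.parametrize("policy", [MatchPolicy.EXACT, MatchPolicy.CATEGORY3])
def test_pipeline_equals_bruteforce_on_random_cohorts(policy):
    rng = random.Random(20180124)
    for _ in range(100):
        cohort, ekb, drug_inds, cmb = _random_world(rng)
        result = run_pipeline(cohort, ekb, policy)
        got_matches = {(m.stay_id, m.cud, m.matching_codes) for m in result.matches}
        got_sugg = {(s.stay_id, s.cud, s.candidate_codes) for s in result.suggestions}
        exp_matches, exp_sugg = _bruteforce(cohort, ekb, drug_inds, cmb, policy)
        assert got_matches == exp_matches
        assert got_sugg == exp_sugg


def test_suggestions_never_duplicate_billing_codes():
    rng = random.Random(42)
    for _ in range(50):
        cohort, ekb, *_ = _random_world(rng)
        result = run_pipeline(cohort, ekb)
        billing = {s.stay_id: s.billing_codes for s in cohort}
        for s in result.suggestions:
            assert not (s.candidate_codes & billing[s.stay_id])


def test_adding_billing_code_never_increases_suggestions():
    rng = random.Random(99)
    for _ in range(40):
        cohort, ekb, *_ = _random_world(rng)
        result = run_pipeline(cohort, ekb)
        base = {}
        for s in result.suggestions:
            base[s.stay_id] = base.get(s.stay_id, 0) + 1
        for stay in list(cohort)[:5]:
            extra = Stay(
                stay_id=stay.stay_id, patient_id=stay.patient_id, admit=stay.admit,
                discharge=stay.discharge,
                billing_codes=stay.billing_codes | {rng.choice(CODE_POOL)},
                prescriptions=stay.prescriptions, labs=stay.labs,
            )
            matches = match_stay(extra, ekb)
            n_after = len(suggest_missing(extra, matches, ekb))
            assert n_after <= base.get(stay.stay_id, 0)


def test_exact_matches_nest_inside_category3():
    rng = random.Random(5)
    for _ in range(50):
        cohort, ekb, *_ = _random_world(rng)
        exact = {(m.stay_id, m.cud) for s in cohort for m in match_stay(s, ekb, MatchPolicy.EXACT) if m.matched}
        cat3 = {(m.stay_id, m.cud) for s in cohort for m in match_stay(s, ekb, MatchPolicy.CATEGORY3) if m.matched}
        assert exact <= cat3
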