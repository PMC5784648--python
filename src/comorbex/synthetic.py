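"""Synthetic knowledge bases, coded cohorts, and deterministic benchmark
fixtures.

Real drug knowledge bases and hospital data warehouses are licensed and
identifiable, so everything here is synthetic. Two layers:

* random generators (:func:`generate_kb`, :func:`generate_cohort`) produce
  cohorts with the statistical structure the detector assumes — drugs
  carrying ICD-10 indication sets, stays whose billing codes omit a tunable
  fraction of the truly present diagnoses (the under-coding rate), and
  per-analyte laboratory models — together with the ground truth needed to
  compute recall;

* deterministic fixture builders (:func:`build_paper_fixture`) lay out four
  reference datasets (``kb_paper``, ``ent``, ``general``, ``hyperkalemia``)
  row by row so that their marginal counts equal the published contingency
  counts of the study the algorithm reproduces. Sampling cannot hit exact
  printed integers, so these are constructed, not drawn; an independent
  audit (:func:`audit_fixture`) re-counts the marginals from the raw CSVs
  with vectorized joins, without touching the detection code.

Fixture codes and drug identifiers are synthetic placeholders except the
anchor triple (SPS-like drug, ICD-10 E87.5, analyte potassium), kept
literal because that rule is the method's worked instance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr import Cohort, LabResult, Prescription, Stay, write_cohort
from .errors import ComorbexError, ConfigError
from .kb import ComorbidityList, DrugRecord
from .evaluate import ReviewLabel, sample_review

__all__ = [
    "SimConfig",
    "LabModel",
    "GroundTruth",
    "generate_kb",
    "generate_cohort",
    "build_paper_fixture",
    "audit_fixture",
    "FIXTURE_NAMES",
    "SPS_CUD",
    "HYPERKALEMIA_CODE",
]

FIXTURE_NAMES = ("kb_paper", "ent", "general", "hyperkalemia")

#: Anchor identifiers for the worked drug+lab rule.
SPS_CUD = "SPS00"
HYPERKALEMIA_CODE = "E875"

#: Internal seed making the "packaged" fixtures (including the general
#: fixture's review sample) identical across builds.
_FIXTURE_SEED = 20180124


# ---------------------------------------------------------------------------
# random generators

@dataclass(frozen=True)
class LabModel:
    """Gaussian lab-value model conditioned on a diagnosis being present."""

    analyte: str
    unit: str
    p_measured: float
    normal_mean: float
    normal_sd: float
    condition_code: str
    condition_mean: float
    condition_sd: float


def _default_lab_models() -> tuple[LabModel, ...]:
    return (
        LabModel(
            analyte="potassium",
            unit="mmol/L",
            p_measured=0.3,
            normal_mean=4.2,
            normal_sd=0.35,
            condition_code=HYPERKALEMIA_CODE,
            condition_mean=5.8,
            condition_sd=0.4,
        ),
    )


def _check_dist(dist: dict[int, float], name: str) -> None:
    if not dist or abs(sum(dist.values()) - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
        raise ConfigError(f"{name}: probabilities must be non-negative and sum to 1")
    if any(int(k) < 0 for k in dist):
        raise ConfigError(f"{name}: counts must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world.

    Defaults emulate the coverage structure of a national drug knowledge
    base (about 90% of drugs carrying an indication, about half linked to a
    major comorbidity) and hospital cohorts where roughly two thirds of
    stays carry at least one prescription without a corresponding billing
    code.
    """

    seed: int = 0
    n_drugs: int = 1000
    p_indication: float = 0.9
    indication_count_distribution: dict = field(
        default_factory=lambda: {1: 0.55, 2: 0.20, 3: 0.10, 5: 0.07, 10: 0.05, 25: 0.03}
    )
    p_comorbidity_indication: float = 0.56
    n_comorbidity_codes: int = 400
    n_other_codes: int = 1600
    n_stays: int = 500
    rx_per_stay_distribution: dict = field(
        default_factory=lambda: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}
    )
    undercoding_rate: float = 0.3
    lab_models: tuple = field(default_factory=_default_lab_models)

    def __post_init__(self) -> None:
        for p, name in (
            (self.p_indication, "p_indication"),
            (self.p_comorbidity_indication, "p_comorbidity_indication"),
            (self.undercoding_rate, "undercoding_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        _check_dist(self.indication_count_distribution, "indication_count_distribution")
        _check_dist(self.rx_per_stay_distribution, "rx_per_stay_distribution")
        if self.n_drugs < 1 or self.n_stays < 0:
            raise ConfigError("n_drugs must be >= 1 and n_stays >= 0")


def _draw(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    return int(rng.choice(keys, p=[dist[k] for k in keys]))


def _code_pools(cfg: SimConfig) -> tuple[list[str], list[str]]:
    comorb = [f"C{i:04d}" for i in range(cfg.n_comorbidity_codes)]
    other = [f"Z{i:04d}" for i in range(cfg.n_other_codes)]
    return comorb, other


def generate_kb(cfg: SimConfig) -> tuple[list[DrugRecord], ComorbidityList]:
    """Sample a drug table and its comorbidity list, reproducibly from seed."""
    rng = np.random.default_rng(cfg.seed)
    comorb_pool, other_pool = _code_pools(cfg)
    drugs: list[DrugRecord] = []
    for i in range(cfg.n_drugs):
        inds: set[str] = set()
        if rng.random() < cfg.p_indication:
            k = _draw(rng, cfg.indication_count_distribution)
            for _ in range(k):
                pool = comorb_pool if rng.random() < cfg.p_comorbidity_indication else other_pool
                inds.add(pool[int(rng.integers(len(pool)))])
        drugs.append(
            DrugRecord(cud=f"CUD{i:06d}", atc="A10BA", label=f"synthetic drug {i}", indications=frozenset(inds))
        )
    return drugs, ComorbidityList(codes=frozenset(comorb_pool))


@dataclass(frozen=True)
class GroundTruth:
    """True and omitted diagnosis sets per stay; billing = true \\ omitted."""

    true_codes: dict[str, frozenset[str]]
    omitted_codes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for sid, omitted in self.omitted_codes.items():
            if not omitted <= self.true_codes[sid]:
                raise ComorbexError(f"stay {sid}: omitted codes not a subset of true codes")

    @property
    def n_missing_stays(self) -> int:
        return sum(1 for o in self.omitted_codes.values() if o)


def generate_cohort(
    cfg: SimConfig, drugs: list[DrugRecord], cmb: ComorbidityList
) -> tuple[Cohort, GroundTruth]:
    """Sample stays whose prescriptions are consistent with drug indications.

    Each prescribed indication-bearing drug contributes one of its
    indications to the stay's true diagnosis set; each true diagnosis is
    then omitted from the billing codes independently with probability
    ``undercoding_rate``. Lab values follow the per-analyte models,
    conditioned on whether the model's condition code is truly present.
    """
    if not drugs:
        raise ConfigError("cannot generate a cohort from an empty knowledge base")
    rng = np.random.default_rng(cfg.seed + 1)
    with_inds = [d for d in drugs if d.indications]
    stays: list[Stay] = []
    true_map: dict[str, frozenset[str]] = {}
    omit_map: dict[str, frozenset[str]] = {}
    admit = date(2015, 1, 1)
    discharge = date(2015, 1, 10)
    for i in range(cfg.n_stays):
        sid = f"S{i:06d}"
        n_rx = _draw(rng, cfg.rx_per_stay_distribution)
        pool = with_inds if with_inds else drugs
        chosen = [pool[int(j)] for j in rng.integers(len(pool), size=n_rx)]
        true: set[str] = set()
        for d in chosen:
            if d.indications:
                inds = sorted(d.indications)
                # prefer a comorbidity-linked indication when one exists, as
                # prescriptions for major conditions are the detection target
                com = sorted(d.indications & cmb.codes)
                true.add(com[int(rng.integers(len(com)))] if com else inds[int(rng.integers(len(inds)))])
        omitted = {c for c in sorted(true) if rng.random() < cfg.undercoding_rate}
        labs: list[LabResult] = []
        for m in cfg.lab_models:
            if rng.random() < m.p_measured:
                has = m.condition_code in true
                mean, sd = (m.condition_mean, m.condition_sd) if has else (m.normal_mean, m.normal_sd)
                value = round(float(rng.normal(mean, sd)), 2)
                labs.append(
                    LabResult(analyte=m.analyte, value=value, unit=m.unit, observed=datetime(2015, 1, 2, 8, 0))
                )
        stays.append(
            Stay(
                stay_id=sid,
                patient_id=f"P{i:06d}",
                admit=admit,
                discharge=discharge,
                billing_codes=frozenset(true - omitted),
                prescriptions=tuple(Prescription(cud=d.cud, start=admit) for d in chosen),
                labs=tuple(labs),
            )
        )
        true_map[sid] = frozenset(true)
        omit_map[sid] = frozenset(omitted)
    cohort = Cohort(stays=tuple(stays), metadata={"source": "synthetic", "seed": cfg.seed})
    return cohort, GroundTruth(true_codes=true_map, omitted_codes=omit_map)


# ---------------------------------------------------------------------------
# deterministic fixtures
#
# Counts below are the published marginals the fixtures encode:
#   kb_paper       22,132 drugs; 19,970 with >=1 indication; 11,162 linked to
#                  a 4,878-code comorbidity list; 4,407 of a 40,000-code
#                  catalogue used as indications.
#   ent            122 stays, 730 billing-code instances of which 339 matched;
#                  92 suggested stays; review: 41 confirmed, 58 codes added,
#                  12 stays gaining a major comorbidity; 43 stays truly missing
#                  a diagnosis.
#   general        4,312 stays, 4,932 code instances of which 1,271 matched;
#                  2,950 suggested stays; 285-stay review sample: 58 confirmed,
#                  76 codes added, 18 major.
#   hyperkalemia   1,270 potassium-measured stays; 152 with K > 5.0 mmol/L and
#                  no E87.5 code; 299 SPS stays, 85 lacking E87.5, 67 of them
#                  with K > 5.0.


def _kb_paper_objects() -> dict:
    catalogue = [f"{letter}{i:04d}" for letter in "ABCD" for i in range(10000)]
    comorb = catalogue[:4878]
    comorb_used = comorb[:2000]
    other_used = [f"B{i:04d}" for i in range(2407)]
    drugs: list[DrugRecord] = []
    for i in range(22132):
        if i < 11162:
            inds = frozenset({comorb_used[i % len(comorb_used)]})
        elif i < 19970:
            j = i - 11162
            inds = frozenset({other_used[j % len(other_used)]})
        else:
            inds = frozenset()
        drugs.append(DrugRecord(cud=f"CUD{i:06d}", atc="A10BA", label=f"synthetic drug {i}", indications=inds))
    return {
        "drugs": drugs,
        "comorbidity_list": ComorbidityList(codes=frozenset(comorb)),
        "catalogue": frozenset(catalogue),
    }


def _matched_drug(slot: int) -> tuple[str, str]:
    """(cud, indication code) for matched-pair slot *slot*."""
    return f"DM{slot:02d}", f"M{slot:02d}0"


_SUGG_DRUG = ("DS00", "S100")      # suggestion drug: comorbidity-linked indication
_NEUTRAL_DRUG = ("DN00", "Q000")   # kept drug, non-comorbid indication
_FILLER_DRUG = ("DF00", "Z500")    # kept drug for hyperkalemia filler stays
_MAJOR_ADDED = "C001"              # reviewer-added code on the comorbidity list
_MINOR_ADDED = ("Z010", "Z020")    # reviewer-added codes off the list


def _unmatched_code(slot: int) -> str:
    return f"U{slot:02d}0"


def _mk_stay(sid: str, codes: set[str], cuds: list[str], labs=(), admit=date(2014, 10, 1)) -> Stay:
    return Stay(
        stay_id=sid,
        patient_id=f"P{sid}",
        admit=admit,
        discharge=date(admit.year, admit.month, admit.day + 9),
        billing_codes=frozenset(codes),
        prescriptions=tuple(Prescription(cud=c, start=admit) for c in cuds),
        labs=tuple(labs),
    )


def _review_labels(
    stay_ids: list[str], n_confirmed: int, n_two_codes: int, n_major: int, n_no_info: int
) -> list[ReviewLabel]:
    """Consensus labels: first *n_confirmed* stays confirmed; the first
    *n_two_codes* of those gain two added codes, the rest one; the first
    *n_major* gain a comorbidity-list code. Rejections split into the two
    observed reasons."""
    labels = []
    for rank, sid in enumerate(stay_ids):
        if rank < n_confirmed:
            codes = {_MAJOR_ADDED if rank < n_major else _MINOR_ADDED[0]}
            if rank < n_two_codes:
                codes.add(_MINOR_ADDED[1])
            labels.append(ReviewLabel(stay_id=sid, reviewer_id="consensus", confirmed=True, added_codes=frozenset(codes)))
        else:
            reason = "no_info" if rank < n_confirmed + n_no_info else "implicit_indication"
            labels.append(
                ReviewLabel(stay_id=sid, reviewer_id="consensus", confirmed=False, rejection_reason=reason)
            )
    return labels


def _ent_objects() -> dict:
    drugs = [
        DrugRecord(cud=_matched_drug(s)[0], atc="A10BA", label=f"matched-pair drug {s}",
                   indications=frozenset({_matched_drug(s)[1]}))
        for s in range(3)
    ]
    drugs.append(DrugRecord(cud=_SUGG_DRUG[0], atc="A10BA", label="suggestion drug", indications=frozenset({_SUGG_DRUG[1]})))
    cmb = ComorbidityList(codes=frozenset({_SUGG_DRUG[1], _MAJOR_ADDED, HYPERKALEMIA_CODE}))

    stays: list[Stay] = []
    sugg_ids: list[str] = []
    for i in range(122):
        sid = f"ENT{i:04d}"
        is_sugg = i < 92
        n_matched = (3 if i < 65 else 2) if is_sugg else 3
        n_unmatched = 4 if i < 25 else 3
        codes = {_matched_drug(s)[1] for s in range(n_matched)}
        codes |= {_unmatched_code(s) for s in range(n_unmatched)}
        cuds = [_matched_drug(s)[0] for s in range(n_matched)]
        if is_sugg:
            cuds.append(_SUGG_DRUG[0])
            sugg_ids.append(sid)
        stays.append(_mk_stay(sid, codes, cuds))
    labels = _review_labels(sugg_ids, n_confirmed=41, n_two_codes=17, n_major=12, n_no_info=31)
    return {
        "drugs": drugs,
        "comorbidity_list": cmb,
        "cohort": Cohort(stays=tuple(stays), metadata={"source": "ent_fixture"}),
        "review": labels,
        "review_sample": sugg_ids,
        "meta": {"n_missing": 43},
    }


def _general_objects() -> dict:
    drugs = [
        DrugRecord(cud="DM00", atc="A10BA", label="matched-pair drug", indications=frozenset({"M100"})),
        DrugRecord(cud=_SUGG_DRUG[0], atc="A10BA", label="suggestion drug", indications=frozenset({_SUGG_DRUG[1]})),
        DrugRecord(cud=_NEUTRAL_DRUG[0], atc="A10BA", label="neutral drug", indications=frozenset({_NEUTRAL_DRUG[1]})),
    ]
    cmb = ComorbidityList(codes=frozenset({_SUGG_DRUG[1], _MAJOR_ADDED, HYPERKALEMIA_CODE}))
    stays: list[Stay] = []
    sugg_ids: list[str] = []
    for i in range(4312):
        sid = f"G{i:05d}"
        codes: set[str] = set()
        cuds: list[str] = []
        if i < 2950:
            cuds.append(_SUGG_DRUG[0])
            sugg_ids.append(sid)
        else:
            cuds.append(_NEUTRAL_DRUG[0])
        if i < 1271:
            cuds.append("DM00")
            codes.add("M100")
        if i < 3661:
            codes.add("U100")
        stays.append(_mk_stay(sid, codes, cuds, admit=date(2015, 1, 1)))
    sample = sample_review(sugg_ids, 285, seed=_FIXTURE_SEED)
    labels = _review_labels(sample, n_confirmed=58, n_two_codes=18, n_major=18, n_no_info=95)
    return {
        "drugs": drugs,
        "comorbidity_list": cmb,
        "cohort": Cohort(stays=tuple(stays), metadata={"source": "general_fixture"}),
        "review": labels,
        "review_sample": sample,
        "meta": {"n_review_sample": 285},
    }


def _hyperkalemia_objects() -> dict:
    drugs = [
        DrugRecord(cud=SPS_CUD, atc="V03AE", label="sodium polystyrene sulfonate (SPS-like)",
                   indications=frozenset({HYPERKALEMIA_CODE})),
        DrugRecord(cud=_FILLER_DRUG[0], atc="A10BA", label="filler drug", indications=frozenset({_FILLER_DRUG[1]})),
    ]
    cmb = ComorbidityList(codes=frozenset({HYPERKALEMIA_CODE, _MAJOR_ADDED}))
    admit = date(2015, 1, 1)

    def k_lab(value: float) -> LabResult:
        return LabResult(analyte="potassium", value=value, unit="mmol/L", observed=datetime(2015, 1, 2, 8, 0))

    stays: list[Stay] = []
    for i in range(1270):
        sid = f"H{i:04d}"
        if i < 214:          # SPS, hyperkalemia coded
            codes, cud, k = {HYPERKALEMIA_CODE}, SPS_CUD, 5.8
        elif i < 281:        # SPS, uncoded, K above threshold -> combined rule fires (67)
            codes, cud, k = set(), SPS_CUD, 5.6
        elif i < 290:        # SPS, uncoded, K exactly at threshold -> never flagged (strict rule)
            codes, cud, k = set(), SPS_CUD, 5.0
        elif i < 299:        # SPS, uncoded, K normal
            codes, cud, k = set(), SPS_CUD, 4.2
        elif i < 384:        # no SPS, uncoded, K above threshold -> lab-only rule fires (85)
            codes, cud, k = set(), _FILLER_DRUG[0], 5.7
        elif i < 394:        # boundary fillers at exactly 5.0
            codes, cud, k = set(), _FILLER_DRUG[0], 5.0
        else:                # unremarkable fillers
            codes, cud, k = set(), _FILLER_DRUG[0], 4.5
        stays.append(_mk_stay(sid, codes, [cud], labs=(k_lab(k),), admit=admit))
    from .detect import hyperkalemia_rules

    return {
        "drugs": drugs,
        "comorbidity_list": cmb,
        "cohort": Cohort(stays=tuple(stays), metadata={"source": "hyperkalemia_fixture"}),
        "rules": hyperkalemia_rules(SPS_CUD),
        "meta": {"n_potassium_stays": 1270, "n_sps_stays": 299},
    }


_BUILDERS = {
    "kb_paper": _kb_paper_objects,
    "ent": _ent_objects,
    "general": _general_objects,
    "hyperkalemia": _hyperkalemia_objects,
}


def fixture_objects(name: str) -> dict:
    """In-memory fixture bundle: drugs, comorbidity list, and (for cohort
    fixtures) cohort/review/rules/meta."""
    if name not in _BUILDERS:
        raise ConfigError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return _BUILDERS[name]()


def _write_drug_table(drugs: list[DrugRecord], path) -> None:
    rows = []
    for d in sorted(drugs, key=lambda d: d.cud):
        if d.indications:
            for ind in sorted(d.indications):
                rows.append({"cud": d.cud, "atc": d.atc, "label": d.label, "indication": ind})
        else:
            rows.append({"cud": d.cud, "atc": d.atc, "label": d.label, "indication": ""})
    pd.DataFrame(rows, columns=["cud", "atc", "label", "indication"]).to_csv(path, index=False)


def write_kb_files(drugs: list[DrugRecord], cmb: ComorbidityList, directory, catalogue=None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_drug_table(drugs, d / "kb.csv")
    pd.DataFrame({"icd10": sorted(cmb.codes)}).to_csv(d / "comorbidity.csv", index=False)
    if catalogue is not None:
        pd.DataFrame({"icd10": sorted(catalogue)}).to_csv(d / "catalogue.csv", index=False)


def build_paper_fixture(name: str, out_dir) -> Path:
    """Write the named fixture's files under *out_dir* and return its path.

    Layout: kb.csv, comorbidity.csv (+ catalogue.csv for kb_paper);
    stays/codes/rx/labs.csv, review.csv, rules.json and meta.json where the
    fixture defines them. Construction is deterministic: identical bytes on
    every build.
    """
    objs = fixture_objects(name)
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_kb_files(objs["drugs"], objs["comorbidity_list"], d, catalogue=objs.get("catalogue"))
    if "cohort" in objs:
        write_cohort(objs["cohort"], d)
    if "review" in objs:
        rows = [
            {
                "stay_id": l.stay_id,
                "reviewer_id": l.reviewer_id,
                "confirmed": int(l.confirmed),
                "added_codes": ";".join(sorted(l.added_codes)),
                "rejection_reason": l.rejection_reason,
            }
            for l in objs["review"]
        ]
        pd.DataFrame(rows, columns=["stay_id", "reviewer_id", "confirmed", "added_codes", "rejection_reason"]).to_csv(
            d / "review.csv", index=False
        )
    if "rules" in objs:
        with open(d / "rules.json", "w") as fh:
            json.dump(
                [
                    {
                        "rule_id": r.rule_id,
                        "trigger_cuds": sorted(r.trigger_cuds),
                        "analyte": r.analyte,
                        "comparator": r.comparator,
                        "threshold": r.threshold,
                        "unit": r.unit,
                        "target_code": r.target_code,
                    }
                    for r in objs["rules"]
                ],
                fh,
                indent=1,
            )
    if "meta" in objs:
        with open(d / "meta.json", "w") as fh:
            json.dump(objs["meta"], fh, indent=1, sort_keys=True)
    return d


# ---------------------------------------------------------------------------
# fixture audit (independent of the detection code: raw-CSV joins only)

_EXPECTED = {
    "kb_paper": {
        "n_drugs": 22132,
        "n_with_indication": 19970,
        "n_comorbidity_linked": 11162,
        "n_catalogue_used": 4407,
        "n_comorbidity_codes": 4878,
    },
    "ent": {"n_stays": 122, "n_code_instances": 730, "n_matched_instances": 339, "n_suggested_stays": 92,
            "n_confirmed": 41, "n_codes_added": 58, "n_major_stays": 12},
    "general": {"n_stays": 4312, "n_code_instances": 4932, "n_matched_instances": 1271,
                "n_suggested_stays": 2950, "n_reviewed": 285, "n_confirmed": 58, "n_codes_added": 76,
                "n_major_stays": 18},
    "hyperkalemia": {"n_stays": 1270, "n_potassium_stays": 1270, "n_high_k_uncoded": 152,
                     "n_sps_stays": 299, "n_sps_uncoded": 85, "n_sps_uncoded_high_k": 67,
                     "n_exact_boundary": 19},
}


def audit_fixture(name: str, directory) -> dict:
    """Re-count a fixture's encoded contingency from its raw CSV files.

    Uses vectorized pandas joins only — none of the kb/detect code paths —
    and raises :class:`ComorbexError` on any mismatch with the expected
    marginals. Returns the realized counts.
    """
    d = Path(directory)
    expected = _EXPECTED.get(name)
    if expected is None:
        raise ConfigError(f"unknown fixture {name!r}")
    kb = pd.read_csv(d / "kb.csv", dtype=str, keep_default_na=False)
    cmb = set(pd.read_csv(d / "comorbidity.csv", dtype=str)["icd10"])
    counts: dict[str, int] = {}

    if name == "kb_paper":
        per_drug = kb.groupby("cud")["indication"].apply(lambda s: {i for i in s if i})
        counts["n_drugs"] = len(per_drug)
        counts["n_with_indication"] = int(per_drug.apply(lambda s: len(s) > 0).sum())
        counts["n_comorbidity_linked"] = int(per_drug.apply(lambda s: bool(s & cmb)).sum())
        catalogue = set(pd.read_csv(d / "catalogue.csv", dtype=str)["icd10"])
        used = set().union(*per_drug) if len(per_drug) else set()
        counts["n_catalogue_used"] = len(catalogue & used)
        counts["n_comorbidity_codes"] = len(cmb)
    else:
        stays = pd.read_csv(d / "stays.csv", dtype=str, keep_default_na=False)
        codes = pd.read_csv(d / "codes.csv", dtype=str, keep_default_na=False)
        rx = pd.read_csv(d / "rx.csv", dtype=str, keep_default_na=False)
        counts["n_stays"] = len(stays)
        if name in ("ent", "general"):
            counts["n_code_instances"] = len(codes.drop_duplicates(["stay_id", "icd10"]))
            # (stay, code) pairs equal to an indication of a drug prescribed in that stay
            kb_pairs = kb[kb["indication"] != ""][["cud", "indication"]]
            stay_inds = rx.merge(kb_pairs, on="cud")[["stay_id", "indication"]].drop_duplicates()
            matched = codes.merge(stay_inds, left_on=["stay_id", "icd10"], right_on=["stay_id", "indication"])
            counts["n_matched_instances"] = len(matched.drop_duplicates(["stay_id", "icd10"]))
            # suggested stays: a prescribed drug with no indication matching any billing
            # code of the stay, and >=1 comorbidity-linked indication not already billed
            billed = codes.groupby("stay_id")["icd10"].apply(set).to_dict()
            kb_ind = kb.groupby("cud")["indication"].apply(lambda s: {i for i in s if i}).to_dict()
            n_sugg = 0
            for sid, grp in rx.groupby("stay_id"):
                b = billed.get(sid, set())
                for cud in set(grp["cud"]):
                    inds = kb_ind.get(cud, set())
                    if inds and not (inds & b) and ((inds & cmb) - b):
                        n_sugg += 1
                        break
            counts["n_suggested_stays"] = n_sugg
            review = pd.read_csv(d / "review.csv", dtype=str, keep_default_na=False)
            conf = review[review["confirmed"] == "1"]
            counts["n_confirmed"] = len(conf)
            counts["n_codes_added"] = int(conf["added_codes"].apply(lambda s: len([c for c in s.split(";") if c])).sum())
            counts["n_major_stays"] = int(
                conf["added_codes"].apply(lambda s: bool(set(s.split(";")) & cmb)).sum()
            )
            if name == "general":
                counts["n_reviewed"] = len(review)
        if name == "hyperkalemia":
            labs = pd.read_csv(d / "labs.csv", dtype=str, keep_default_na=False)
            k = labs[labs["analyte"] == "potassium"].copy()
            k["value"] = k["value"].astype(float)
            measured = set(k["stay_id"])
            counts["n_potassium_stays"] = len(measured)
            coded = set(codes[codes["icd10"] == HYPERKALEMIA_CODE]["stay_id"])
            kmax = k.groupby("stay_id")["value"].max()
            high = set(kmax[kmax > 5.0].index)
            counts["n_high_k_uncoded"] = len((high & measured) - coded)
            sps = set(rx[rx["cud"] == SPS_CUD]["stay_id"])
            counts["n_sps_stays"] = len(sps)
            counts["n_sps_uncoded"] = len(sps - coded)
            counts["n_sps_uncoded_high_k"] = len((sps - coded) & high)
            counts["n_exact_boundary"] = int((kmax == 5.0).sum())

    mismatches = {k: (counts.get(k), v) for k, v in expected.items() if counts.get(k) != v}
    if mismatches:
        raise ComorbexError(f"fixture {name} audit failed: {{realized, expected}} = {mismatches}")
    return counts
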