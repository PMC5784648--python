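"""Drug knowledge base and comorbidity-list enrichment (step 1).

A drug knowledge base maps each dispensation unit (CUD — the French
per-product drug identifier) to its therapeutic class (ATC code) and the
set of ICD-10 codes it is indicated for. Enrichment intersects each drug's
indications with a national list of major comorbid conditions, after
excluding drugs whose indications are too broad or too unspecific to point
at a particular diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import CodeValidationError, ComorbexError, ConfigError
from .icd10 import normalize_code, normalize_codes
from .rounding import pct, round1

__all__ = [
    "DrugRecord",
    "ComorbidityList",
    "ExclusionConfig",
    "EnrichedKnowledgeBase",
    "KbCoverageStats",
    "load_drug_table",
    "load_comorbidity_list",
    "apply_exclusions",
    "enrich",
    "coverage_stats",
    "build_enriched_kb",
    "write_enriched_kb",
]

logger = logging.getLogger(__name__)

#: Exclusion reason tags, in precedence order (first match wins).
EXCLUSION_REASONS = ("atc_class", "broad", "imprecise_only", "no_indication")

#: Documented default for symptomatic therapeutic classes whose drugs are
#: excluded from matching. This is a heuristic stand-in for the (licensed,
#: unpublished) reference exclusion list, NOT that list: broad analgesics
#: (N02B), cough/cold preparations (R05), antipyretic combinations.
DEFAULT_EXCLUDED_ATC_PREFIXES = frozenset({"N02B", "R05"})


@dataclass(frozen=True)
class DrugRecord:
    """One dispensation-unit drug with its class and indication set."""

    cud: str
    atc: str
    label: str
    indications: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indications", frozenset(self.indications))


@dataclass(frozen=True)
class ComorbidityList:
    """Flat set of ICD-10 codes flagged as major comorbid conditions."""

    codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ConfigError("comorbidity list must be non-empty")
        object.__setattr__(self, "codes", normalize_codes(self.codes))

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self.codes

    def __len__(self) -> int:
        return len(self.codes)


def _default_imprecise_codes() -> frozenset[str]:
    """Heuristic default for 'imprecise' indications.

    The canonical example is R52.9 'Pain, unspecified'. As a documented
    stand-in for the unpublished reference enumeration, treat symptom-chapter
    (R) codes whose fourth character is '9' (the ICD-10 'unspecified'
    residual) as imprecise.
    """
    return frozenset(f"R{i:02d}9" for i in range(100))


@dataclass(frozen=True)
class ExclusionConfig:
    """Rules deciding which drugs are unusable for comorbidity detection."""

    max_indications: int = 20
    imprecise_codes: frozenset[str] = field(default_factory=_default_imprecise_codes)
    excluded_atc_prefixes: frozenset[str] = DEFAULT_EXCLUDED_ATC_PREFIXES

    def __post_init__(self) -> None:
        if self.max_indications < 1:
            raise ConfigError("max_indications must be >= 1")
        object.__setattr__(self, "imprecise_codes", normalize_codes(self.imprecise_codes))
        object.__setattr__(
            self, "excluded_atc_prefixes", frozenset(str(p).upper() for p in self.excluded_atc_prefixes)
        )


@dataclass(frozen=True)
class EnrichedKnowledgeBase:
    """Post-exclusion drug→indication map with comorbidity-linked subsets.

    ``drugs`` and ``excluded`` partition the input drug set; for every kept
    drug, ``comorbid_indications[cud]`` is the subset of its indications
    present on the comorbidity list (possibly empty).
    """

    drugs: dict[str, DrugRecord]
    comorbid_indications: dict[str, frozenset[str]]
    excluded: dict[str, str]  # cud -> exclusion reason tag
    excluded_records: dict[str, DrugRecord] = field(default_factory=dict)

    def is_kept(self, cud: str) -> bool:
        return cud in self.drugs

    def indications(self, cud: str) -> frozenset[str]:
        return self.drugs[cud].indications

    @property
    def all_records(self) -> list[DrugRecord]:
        return list(self.drugs.values()) + list(self.excluded_records.values())


@dataclass(frozen=True)
class KbCoverageStats:
    """Headline coverage counts/percentages over the whole input drug table."""

    n_drugs: int
    n_with_indication: int
    n_comorbidity_linked: int
    n_catalogue: int
    n_catalogue_used: int
    pct_with_indication: float
    pct_comorbidity_linked: float
    pct_catalogue_used: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def load_drug_table(path, dialect: dict | None = None) -> list[DrugRecord]:
    """Read a drug table CSV into DrugRecords.

    Expects columns ``cud, atc, label, indication`` with one row per
    drug–indication pair; a drug without indications appears once with an
    empty indication cell. Rows are grouped by CUD and indications
    normalized/deduplicated.
    """
    opts = {"dtype": str, "keep_default_na": False}
    opts.update(dialect or {})
    try:
        df = pd.read_csv(path, **opts)
    except OSError as exc:
        raise ComorbexError(f"cannot read drug table {path}: {exc}") from exc
    required = {"cud", "atc", "label", "indication"}
    missing = required - set(df.columns)
    if missing:
        raise ComorbexError(f"drug table {path} lacks columns: {sorted(missing)}")

    records: list[DrugRecord] = []
    for cud, grp in df.groupby("cud", sort=True):
        atcs = set(grp["atc"].str.strip())
        if len(atcs) > 1:
            raise ComorbexError(f"duplicate cud {cud!r} with conflicting ATC codes {sorted(atcs)}")
        inds = set()
        for raw in grp["indication"]:
            raw = raw.strip()
            if raw:
                inds.add(normalize_code(raw))
        records.append(
            DrugRecord(cud=str(cud), atc=atcs.pop(), label=grp["label"].iloc[0], indications=frozenset(inds))
        )
    logger.info("loaded %d rows -> %d drugs from %s", len(df), len(records), path)
    return records


def load_comorbidity_list(path) -> ComorbidityList:
    """Read a single-column ``icd10`` CSV into a ComorbidityList."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "icd10" not in df.columns:
        raise ComorbexError(f"comorbidity list {path} lacks an 'icd10' column")
    return ComorbidityList(codes=frozenset(c for c in df["icd10"].str.strip() if c))


def exclusion_reason(drug: DrugRecord, cfg: ExclusionConfig) -> str | None:
    """Reason tag for excluding *drug*, or None if it is kept.

    Precedence (first match wins): atc_class > broad > imprecise_only >
    no_indication. "Broad" is a strict threshold: a drug with exactly
    ``max_indications`` indications is kept.
    """
    atc = drug.atc.upper()
    if any(atc.startswith(p) for p in cfg.excluded_atc_prefixes):
        return "atc_class"
    if len(drug.indications) > cfg.max_indications:
        return "broad"
    if drug.indications and drug.indications <= cfg.imprecise_codes:
        return "imprecise_only"
    if not drug.indications:
        return "no_indication"
    return None


def apply_exclusions(
    drugs: list[DrugRecord], cfg: ExclusionConfig | None = None
) -> tuple[list[DrugRecord], dict[str, str]]:
    """Partition drugs into (kept, {cud: reason}) under the exclusion rules."""
    cfg = cfg or ExclusionConfig()
    kept: list[DrugRecord] = []
    excluded: dict[str, str] = {}
    for d in drugs:
        reason = exclusion_reason(d, cfg)
        if reason is None:
            kept.append(d)
        else:
            excluded[d.cud] = reason
    return kept, excluded


def enrich(kept: list[DrugRecord], cmb: ComorbidityList) -> EnrichedKnowledgeBase:
    """Intersect each kept drug's indications with the comorbidity list."""
    if not kept:
        raise ConfigError("no kept drugs to enrich")
    drugs = {d.cud: d for d in sorted(kept, key=lambda d: d.cud)}
    if len(drugs) != len(kept):
        raise ComorbexError("duplicate cud among kept drugs")
    comorbid = {cud: d.indications & cmb.codes for cud, d in drugs.items()}
    return EnrichedKnowledgeBase(drugs=drugs, comorbid_indications=comorbid, excluded={})


def build_enriched_kb(
    drugs: list[DrugRecord], cmb: ComorbidityList, cfg: ExclusionConfig | None = None
) -> EnrichedKnowledgeBase:
    """Exclusion + enrichment in one step, retaining excluded records."""
    kept, excluded = apply_exclusions(drugs, cfg)
    ekb = enrich(kept, cmb) if kept else EnrichedKnowledgeBase({}, {}, {})
    by_cud = {d.cud: d for d in drugs}
    return EnrichedKnowledgeBase(
        drugs=ekb.drugs,
        comorbid_indications=ekb.comorbid_indications,
        excluded=excluded,
        excluded_records={cud: by_cud[cud] for cud in excluded},
    )


def coverage_stats(ekb: EnrichedKnowledgeBase, catalogue: frozenset[str] | set[str]) -> KbCoverageStats:
    """Coverage over ALL input drugs (kept and excluded alike).

    ``pct_catalogue_used`` is the share of a reference code catalogue (e.g.
    the ~40,000-code national ICD-10) appearing as at least one drug
    indication.
    """
    if not catalogue:
        raise ConfigError("catalogue must be non-empty")
    catalogue = normalize_codes(catalogue)
    records = ekb.all_records
    n = len(records)
    if n == 0:
        raise ComorbexError("knowledge base contains no drugs")
    n_with = sum(1 for d in records if d.indications)
    cmb_map = ekb.comorbid_indications
    n_com = sum(1 for d in records if cmb_map.get(d.cud))
    used = frozenset().union(*(d.indications for d in records)) if records else frozenset()
    n_used = len(catalogue & used)
    return KbCoverageStats(
        n_drugs=n,
        n_with_indication=n_with,
        n_comorbidity_linked=n_com,
        n_catalogue=len(catalogue),
        n_catalogue_used=n_used,
        pct_with_indication=round1(pct(n_with, n)),
        pct_comorbidity_linked=round1(pct(n_com, n)),
        pct_catalogue_used=round1(pct(n_used, len(catalogue))),
    )


def write_enriched_kb(ekb: EnrichedKnowledgeBase, path) -> None:
    """Write the enriched KB as one row per drug–indication pair.

    Columns: cud, atc, label, indication, is_comorbidity, excluded,
    exclusion_reason. Deterministically sorted by (cud, indication).
    """
    rows = []
    for d in sorted(ekb.all_records, key=lambda d: d.cud):
        excl = ekb.excluded.get(d.cud, "")
        comorb = ekb.comorbid_indications.get(d.cud, frozenset())
        if d.indications:
            for ind in sorted(d.indications):
                rows.append(
                    {
                        "cud": d.cud,
                        "atc": d.atc,
                        "label": d.label,
                        "indication": ind,
                        "is_comorbidity": int(ind in comorb),
                        "excluded": int(bool(excl)),
                        "exclusion_reason": excl,
                    }
                )
        else:
            rows.append(
                {
                    "cud": d.cud,
                    "atc": d.atc,
                    "label": d.label,
                    "indication": "",
                    "is_comorbidity": 0,
                    "excluded": int(bool(excl)),
                    "exclusion_reason": excl,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_enriched_kb(path) -> EnrichedKnowledgeBase:
    """Load an enriched KB written by :func:`write_enriched_kb`."""
    df = pd.read_csv(path, dtype={"cud": str, "atc": str, "label": str, "indication": str}, keep_default_na=False)
    drugs: dict[str, DrugRecord] = {}
    comorbid: dict[str, frozenset[str]] = {}
    excluded: dict[str, str] = {}
    excluded_records: dict[str, DrugRecord] = {}
    for cud, grp in df.groupby("cud", sort=True):
        inds = frozenset(i for i in grp["indication"] if i)
        rec = DrugRecord(cud=str(cud), atc=grp["atc"].iloc[0], label=grp["label"].iloc[0], indications=inds)
        if int(grp["excluded"].iloc[0]):
            excluded[str(cud)] = grp["exclusion_reason"].iloc[0]
            excluded_records[str(cud)] = rec
        else:
            drugs[str(cud)] = rec
            comorbid[str(cud)] = frozenset(
                i for i, is_c in zip(grp["indication"], grp["is_comorbidity"]) if i and int(is_c)
            )
    return EnrichedKnowledgeBase(
        drugs=drugs, comorbid_indications=comorbid, excluded=excluded, excluded_records=excluded_records
    )
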