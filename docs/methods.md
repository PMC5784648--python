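# Methods

## The detection model

`comorbex` treats under-coding as a reconciliation problem between two
structured views of a hospital stay: what was billed (ICD-10 codes) and
what was done (drug prescriptions, laboratory results). The model is
deliberately rule-based and deterministic — every flagged stay can be
explained by pointing at a prescription or a lab value — because the
output is consumed by human coders, not by a downstream classifier.

**Step 1 (enrichment)** builds the mapping `drug → candidate diagnoses`.
A drug is usable for detection only if its indication set is informative:
drugs with more than `max_indications` (default 20, a *strict* threshold —
exactly 20 is kept) indications, drugs whose indications are *only*
unspecific symptom codes, and drugs in excluded therapeutic classes (ATC
prefix match) are removed. Exclusion reasons are assigned with fixed
precedence `atc_class > broad > imprecise_only > no_indication` so reports
are deterministic; the precedence order itself is a presentation choice —
it never changes *which* drugs are kept, only how an exclusion is labeled.
Each kept drug's indications are intersected with the major-comorbidity
list; that intersection is what the detector may suggest.

Two inputs of the real deployment are licensed and unpublished, so their
configuration defaults are documented heuristic stand-ins, not the
reference lists: `excluded_atc_prefixes` defaults to two symptomatic
classes (N02B broad analgesics, R05 cough preparations), and
`imprecise_codes` defaults to symptom-chapter (R) codes whose fourth
character is the ICD-10 "unspecified" residual 9 (the canonical example
being R52.9, "pain, unspecified"). Both are plain config sets; production
users supply their own.

**Step 2 (matching)** is within-stay only: a billing code matches a
prescription if some indication of the prescribed drug equals it under the
match policy. The default policy is `exact` (normalized string equality) —
the conservative choice, since coarser matching makes fewer prescriptions
look unmatched and therefore suggests less, at the price of missing
specificity mismatches. `category3` (equality of the three-character ICD-10
category) is provided for sensitivity analysis; exact matches are provably
a subset of category matches, and the tests assert this nesting. Repeat
prescriptions of one drug within a stay collapse to a single match/
suggestion, and prescriptions of drugs absent from the knowledge base are
skipped with a report rather than failing — real extracts always contain
them. A suggestion's candidate set is the drug's comorbidity-linked
indications minus the codes already billed, so no suggestion can duplicate
an existing code (a tested invariant).

**Step 3 (drug + lab fusion)** is a small rule engine. A rule names an
analyte, a comparator (`gt|ge|lt|le`), a threshold with unit, a target
ICD-10 code, and an optional trigger drug set; an empty trigger set makes
the rule lab-only. The shipped instance is hyperkalemia: potassium
strictly greater than 5.0 mmol/L (the French nephrology definition), with
or without a sodium-polystyrene-sulfonate trigger, targeting E87.5. The
comparator is strict, and the benchmark fixture contains stays at exactly
5.0 mmol/L to pin that boundary. Evidence reported to the reviewer is the
extremal qualifying value (maximum for `gt`/`ge`, minimum for `lt`/`le`).
Only results timestamped within `[admit, discharge]` qualify; no lookback
window is applied. Rule thresholds must be stated in the canonical unit
declared for the analyte, and cohort lab rows in any other unit are
rejected at load time — silent unit mixing is the classic failure mode of
threshold rules.

Cohort inclusion mirrors the deployment's flow: a stay enters detection
only if it has at least one prescription, at least one prescription of a
kept drug, and at least one of those kept drugs carries indications;
removals are counted under the first failing reason. In `run_pipeline` the
lab rules run over this included cohort, consistent with applying step 3
to the same stay-filtered study population as step 2.

## Evaluation metrics

The metric unit is the stay. Precision = confirmed/suggested stays,
recall = confirmed/truly-missing stays (computable only when ground truth
exists — chart review or synthetic cohorts), F = harmonic mean. All three
are computed from the *unrounded* ratios and only then rounded half-up to
one decimal; rounding precision and recall before taking the harmonic mean
can shift the F-score's last digit. Because published precision figures
sometimes truncate rather than round (58/285 = 20.35% may be reported as
20.3), the report carries the raw ratio plus both the half-up and the
truncated one-decimal values.

Cohen's κ is implemented directly — (p_o − p_e)/(1 − p_e) with p_e from
the marginal products — with a 95% CI from the standard asymptotic
standard error `sqrt(p_o(1−p_o)/(n(1−p_e)²))`; the test suite cross-checks
the point estimate against scikit-learn's independent implementation.
Degenerate marginals (p_e = 1) raise instead of returning a meaningless
value. With rare positives, κ's CI from this SE is wide; alternative SE
formulas exist and can differ noticeably at extreme marginals.

## The synthetic layer

The random generators emulate the *statistical shape* the detector
assumes, not real content: synthetic CUDs, a code pool split into a
comorbidity list and other codes, drugs carrying indication sets (default:
90% of drugs indication-bearing; 56% of indications drawn from the
comorbidity pool, which makes roughly half of all drugs
comorbidity-linked, matching the coverage structure of a national drug
knowledge base), and stays whose true diagnoses derive from their
prescriptions. Under-coding is the single dial: each true diagnosis is
omitted from billing independently with probability `undercoding_rate`
(default 0.3, which yields suggestion rates in the range observed in
practice). Ground truth (true and omitted code sets per stay) is emitted
alongside, so billing = true \ omitted holds by construction and recall is
computable. Lab values are Gaussian per analyte, conditioned on whether
the rule's condition code is truly present. What this does *not* emulate:
real ICD-10 prevalence, co-prescription correlations, off-label
prescribing, free-text evidence, and cross-stay patient history — so
passing tests show algorithmic correctness under the stated generative
assumptions, not clinical performance on real records.

The four benchmark fixtures (`kb_paper`, `ent`, `general`,
`hyperkalemia`) are *constructed*, not sampled: sampling cannot hit exact
published integers. Each lays out rows deterministically so that the
marginal counts equal the published contingencies (e.g. 122 stays / 730
code instances / 339 matched / 92 suggested for the ENT benchmark; 22,132
drugs / 19,970 indication-bearing / 11,162 comorbidity-linked for the
knowledge base). The joint layout behind those marginals is
under-determined by the published counts; any layout satisfying the
marginals is acceptable, and an independent audit (`audit_fixture`,
vectorized pandas joins over the raw CSVs, sharing no code with the
detector) verifies exactly the marginals before the fixtures are used.
Fixture codes and identifiers are synthetic placeholders except the
anchor triple (SPS-like drug, E87.5, potassium). The general fixture's
285-stay review sample is drawn once with a fixed internal seed and is
part of the fixture definition. Fixtures are generated at run time (the
knowledge-base table alone would be ~800 KB on disk), which also keeps
them trivially in sync with the code.

## Numerical and I/O choices

- Percentages are presented rounded half-up to one decimal via
  `decimal.Decimal` (banker's rounding would disagree on exact halves).
- All ICD-10 handling is on normalized codes (uppercase, dot stripped);
  normalization is idempotent and malformed codes fail loudly at parse
  time, naming the offending value.
- Detected-code fractions count distinct (stay, code) pairs, so duplicate
  code rows cannot inflate either numerator or denominator.
- All file outputs (cohort files, enriched KB, suggestions) are sorted on
  stable keys before writing, making runs byte-identical — reproducibility
  is checked at the file-checksum level in the CLI tests.
- Orphan rows (codes/rx/labs referencing no stay) fail loudly by default
  (`orphan_tolerance = 0`) with a listing of the offending rows.
- Degenerate denominators (no drugs, no billing codes, no suggested
  stays, p_e = 1) raise typed errors rather than returning NaN.

## Known limitations

- Only official indications drive detection; off-label prescribing is
  invisible and produces either silence or a wrong suggestion — a
  structural limit of indication-based detection, delegated to the human
  reviewer.
- Matching is within-stay; evidence in a patient's earlier stays is out of
  scope for the detector (reviewers may still use it).
- One lab rule family ships (hyperkalemia); the engine is generic but each
  new rule needs a clinically validated threshold and canonical unit.
- The improvement of combined drug+lab detection over lab-only detection
  is reported as raw counts per rule (eligible and flagged stays), not as
  a single derived percentage.
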