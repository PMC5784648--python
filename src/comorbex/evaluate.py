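"""Evaluation of suggested diagnoses against expert chart review.

The metric unit is the stay: a suggested stay is confirmed when the
reviewers accept at least one of its candidate codes. Precision is
confirmed/suggested, recall is confirmed over stays with truly missing
diagnoses (known only when ground truth exists — chart review or synthetic
cohorts), and the F-score is their harmonic mean. Inter-observer agreement
is Cohen's kappa over the two reviewers' per-stay confirm/reject flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .icd10 import normalize_codes
from .kb import ComorbidityList
from .rounding import pct, round1, trunc1

__all__ = [
    "ReviewLabel",
    "EvaluationReport",
    "KappaResult",
    "read_review_labels",
    "compute_metrics",
    "f_score",
    "cohen_kappa",
    "sample_review",
]

REJECTION_REASONS = ("no_info", "implicit_indication", "none")


@dataclass(frozen=True)
class ReviewLabel:
    """Consensus review outcome for one suggested stay."""

    stay_id: str
    reviewer_id: str
    confirmed: bool
    added_codes: frozenset[str] = frozenset()
    rejection_reason: str = "none"

    def __post_init__(self) -> None:
        if self.rejection_reason not in REJECTION_REASONS:
            raise EvaluationError(f"unknown rejection reason {self.rejection_reason!r}")
        object.__setattr__(self, "added_codes", normalize_codes(self.added_codes))
        if self.confirmed and (not self.added_codes or self.rejection_reason != "none"):
            raise EvaluationError(f"stay {self.stay_id}: confirmed label needs added codes and no rejection reason")


@dataclass(frozen=True)
class EvaluationReport:
    """Per-stay precision/recall/F plus added-code tallies.

    ``precision_raw`` keeps the unrounded ratio because published figures
    round inconsistently (half-up vs truncation) at the second decimal;
    rounded fields use half-up, and ``precision_truncated`` is provided for
    comparison with truncated presentations.
    """

    n_suggested: int
    n_confirmed: int
    n_missing: int | None
    precision: float
    precision_raw: float
    precision_truncated: float
    recall: float | None
    f_score: float | None
    n_codes_added: int
    n_major_added: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def summary(self) -> str:
        lines = [
            f"suggested stays : {self.n_suggested}",
            f"confirmed stays : {self.n_confirmed}",
            f"precision       : {self.precision}% (raw {self.precision_raw:.4f}%, truncated {self.precision_truncated}%)",
        ]
        if self.recall is not None:
            lines.append(f"recall          : {self.recall}% (missing stays: {self.n_missing})")
            lines.append(f"F-score         : {self.f_score}%")
        lines.append(f"codes added     : {self.n_codes_added} ({self.n_major_added} stays gained a major comorbidity)")
        return "\n".join(lines)


def read_review_labels(path) -> list[ReviewLabel]:
    """Read ``review.csv``: stay_id,reviewer_id,confirmed,added_codes,rejection_reason
    (added codes semicolon-joined)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    labels = []
    for row in df.itertuples(index=False):
        codes = frozenset(c for c in str(row.added_codes).split(";") if c)
        labels.append(
            ReviewLabel(
                stay_id=row.stay_id,
                reviewer_id=row.reviewer_id,
                confirmed=str(row.confirmed).strip().lower() in ("1", "true", "yes"),
                added_codes=codes,
                rejection_reason=row.rejection_reason or "none",
            )
        )
    return labels


def f_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall on the percentage scale."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def compute_metrics(
    labels: list[ReviewLabel],
    n_suggested: int,
    n_missing: int | None = None,
    comorbidity_list: ComorbidityList | None = None,
) -> EvaluationReport:
    """Precision (and recall/F when ground truth is known) from consensus labels.

    Precision and recall are computed from the unrounded ratios and the
    F-score from those unrounded values, then each is rounded half-up to one
    decimal — rounding precision and recall first and then taking the
    harmonic mean can shift the F-score's final digit.
    """
    if n_suggested <= 0:
        raise EvaluationError("n_suggested must be positive")
    seen = [l.stay_id for l in labels]
    if len(seen) != len(set(seen)):
        raise EvaluationError("labels must be deduplicated to one consensus label per stay")
    n_confirmed = sum(1 for l in labels if l.confirmed)
    if n_confirmed > n_suggested:
        raise EvaluationError("more confirmed than suggested stays")
    p_raw = pct(n_confirmed, n_suggested)
    recall = f = None
    if n_missing is not None:
        if n_missing <= 0:
            raise EvaluationError("recall requested with n_missing <= 0")
        r_raw = pct(n_confirmed, n_missing)
        recall = round1(r_raw)
        f = round1(f_score(p_raw, r_raw))
    n_codes = sum(len(l.added_codes) for l in labels if l.confirmed)
    if comorbidity_list is not None:
        n_major = sum(1 for l in labels if l.confirmed and (l.added_codes & comorbidity_list.codes))
    else:
        n_major = 0
    return EvaluationReport(
        n_suggested=n_suggested,
        n_confirmed=n_confirmed,
        n_missing=n_missing,
        precision=round1(p_raw),
        precision_raw=p_raw,
        precision_truncated=trunc1(p_raw),
        recall=recall,
        f_score=f,
        n_codes_added=n_codes,
        n_major_added=n_major,
    )


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_expected: float
    n: int


def cohen_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa for two reviewers' per-stay binary flags.

    kappa = (p_o - p_e)/(1 - p_e) with p_e from the product of marginals;
    the 95% CI uses the asymptotic standard error
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise EvaluationError("reviewer label vectors must be equal-length, non-empty")
    n = a.size
    p_o = float(np.mean(a == b))
    pa, pb = float(np.mean(a)), float(np.mean(b))
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        raise EvaluationError("degenerate marginals: chance agreement is 1, kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    return KappaResult(
        kappa=kappa,
        se=se,
        ci_low=kappa - 1.96 * se,
        ci_high=kappa + 1.96 * se,
        p_observed=p_o,
        p_expected=p_e,
        n=n,
    )


def sample_review(suggested_stays: list, n: int, seed: int) -> list:
    """Uniform sample without replacement of stays to send for review."""
    if n > len(suggested_stays):
        raise EvaluationError(f"cannot sample {n} from {len(suggested_stays)} suggested stays")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(suggested_stays), size=n, replace=False)
    return [suggested_stays[i] for i in sorted(idx)]
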