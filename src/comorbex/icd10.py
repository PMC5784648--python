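"""ICD-10 code normalization.

Codes are handled as plain strings in a canonical form: uppercase, dot and
surrounding whitespace removed ("e87.5" and "E875" are the same diagnosis).
All set membership and equality throughout the package is on normalized
codes.
"""

from __future__ import annotations

import re

from .errors import CodeValidationError

__all__ = ["normalize_code", "normalize_codes", "is_valid_code"]

# leading letter, two digits, then optional alphanumerics (post-normalization)
_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]*$")


def normalize_code(raw: str) -> str:
    """Return the canonical form of an ICD-10 code.

    Uppercases, strips whitespace and removes dots. Idempotent. Raises
    :class:`CodeValidationError` for values that cannot be an ICD-10 code
    (no leading letter, fewer than three characters).
    """
    if raw is None:
        raise CodeValidationError("ICD-10 code is missing")
    code = str(raw).strip().upper().replace(".", "")
    if not _CODE_RE.match(code):
        raise CodeValidationError(f"malformed ICD-10 code: {raw!r}")
    return code


def normalize_codes(raws) -> frozenset[str]:
    """Normalize an iterable of codes into a deduplicated frozenset."""
    return frozenset(normalize_code(r) for r in raws)


def is_valid_code(raw: str) -> bool:
    """True if *raw* normalizes to a well-formed code."""
    try:
        normalize_code(raw)
    except CodeValidationError:
        return False
    return True
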