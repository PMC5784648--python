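"""Exception hierarchy for comorbex."""


class ComorbexError(Exception):
    """Base class for all comorbex errors."""


class CodeValidationError(ComorbexError):
    """A diagnosis code does not conform to the ICD-10 shape."""


class ConfigError(ComorbexError):
    """Invalid configuration (exclusion rules, lab rules, simulation)."""


class CohortValidationError(ComorbexError):
    """A cohort extract violates referential or unit constraints."""


class EvaluationError(ComorbexError):
    """Evaluation metrics requested on degenerate denominators."""
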