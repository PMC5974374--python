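"""Exception hierarchy for e2fsig.

All errors raised on purpose by the package derive from :class:`E2FSigError`
so callers (and the CLI) can distinguish expected analysis failures from
bugs.
"""


class E2FSigError(Exception):
    """Base class for all e2fsig errors."""


class ConfigError(E2FSigError):
    """Invalid simulation or pipeline configuration."""


class MatrixFormatError(E2FSigError):
    """Malformed expression matrix / annotation file (duplicate IDs,
    missing values, non-numeric cells).  Messages name the offending
    row/column with 1-based line numbers where possible."""


class PairingError(E2FSigError):
    """Replicate column that cannot be assigned to a sample, or a sample
    with no replicate columns."""


class GMTFormatError(E2FSigError):
    """Malformed GMT gene-set line (fewer than 3 fields, empty member
    list)."""


class ClassificationError(E2FSigError):
    """Signature cannot be applied (all up or all down markers missing,
    or every ratio undefined for a sample)."""


class SurvivalError(E2FSigError):
    """Degenerate survival input (no events, fewer than two groups)."""


class NoInhibitionError(E2FSigError):
    """Dose-response series with a flat response; IC50 undefined."""


class ParameterError(E2FSigError):
    """Out-of-range analysis parameter (k > n samples, empty group,
    thresholds outside their domain)."""
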