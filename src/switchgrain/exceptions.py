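"""Exception hierarchy.

Everything raised on purpose by the package derives from
:class:`SwitchgrainError`, so callers can catch one type at pipeline
boundaries while tests can assert on the specific failure mode.
"""


class SwitchgrainError(Exception):
    """Base class for all errors raised by switchgrain."""


class FormatError(SwitchgrainError):
    """A file or record violates its format contract (duplicates, negatives,
    missing cells, illegal residues, ...)."""


class DesignError(SwitchgrainError):
    """Data is inconsistent with the study design (column mismatch, too few
    replicates, wrong number of per-column factors, ...)."""


class ConfigError(SwitchgrainError):
    """A configuration object is internally invalid or infeasible."""


class CorrectionError(SwitchgrainError):
    """A normalization scheme cannot be applied (e.g. a reference gene with a
    zero count in some column)."""


class DiagnosticError(SwitchgrainError):
    """A reproducibility/bias metric is undefined for the given data."""


class EstimationError(SwitchgrainError):
    """A model parameter cannot be estimated from the given data."""


class AnnotationError(SwitchgrainError):
    """An event refers to annotation that does not exist."""


class SelectionError(SwitchgrainError):
    """A selection rule has nothing to select from."""
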