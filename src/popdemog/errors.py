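"""Exception hierarchy shared across the package."""


class PopdemogError(Exception):
    """Base class for all package errors."""


class FormatError(PopdemogError):
    """Malformed input file (empty FASTA, bad TSV header, ...)."""


class AlignmentError(PopdemogError):
    """Sequences that should form an alignment do not (unequal lengths, <2 rows)."""


class ReconciliationError(PopdemogError):
    """Sample labels in sequence files and the population map disagree."""


class ParameterError(PopdemogError):
    """Invalid demographic parameters."""


class ConfigError(PopdemogError):
    """Invalid run configuration (priors, time-scale constants, ...)."""


class EstimationError(PopdemogError):
    """An estimator could not produce a result (too few samples, non-convergence)."""
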