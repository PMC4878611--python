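"""Exception hierarchy shared across the package."""


class RepbenchError(Exception):
    """Base class for all package errors."""


class FormatError(RepbenchError):
    """Malformed input file (bad counts, duplicate identifiers, wrong columns)."""


class ConsistencyError(RepbenchError):
    """Inputs that are individually valid but disagree with each other."""


class DesignError(RepbenchError):
    """Invalid sample-to-condition assignment."""


class NormalizationError(RepbenchError):
    """Size factors cannot be computed (e.g. no zero-free reference gene)."""


class RegistryError(RepbenchError):
    """Unknown differential-expression caller name."""


class ContractError(RepbenchError):
    """A caller or plugin returned a malformed result table."""


class ConstantRowError(RepbenchError):
    """A zero-variance SDE vector for which correlation distance is undefined."""


class BenchmarkError(RepbenchError):
    """Invalid benchmark request (empty threshold universe, n_r out of range)."""


class ConfigError(RepbenchError):
    """Invalid generator or pipeline configuration; carries the full error list."""

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class PipelineError(RepbenchError):
    """A pipeline stage failed; the message names the stage."""
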