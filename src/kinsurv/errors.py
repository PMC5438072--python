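"""Exception hierarchy for kinsurv."""


class KinsurvError(Exception):
    """Base class for all kinsurv errors."""


class InvalidParameterError(KinsurvError, ValueError):
    """A parameter is outside its admissible range."""


class ConfigurationError(KinsurvError, ValueError):
    """Inconsistent or incomplete configuration."""


class FormatError(KinsurvError, ValueError):
    """An input file or table violates the expected schema."""


class AlignmentError(KinsurvError, ValueError):
    """Genotype and phenotype tables cannot be aligned on subject ids."""


class DegenerateDataError(KinsurvError, ValueError):
    """The data carry no information for the requested estimate."""


class ConvergenceError(KinsurvError, RuntimeError):
    """Iterative fitting failed to converge."""


class ConsistencyError(KinsurvError, ValueError):
    """A fitted object was applied to records it was not fitted on."""
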