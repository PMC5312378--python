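"""Exception hierarchy.

Exit-code mapping for the CLI: configuration errors (2), alignment errors
(3), inference errors (4); anything else propagates as a crash (1).
"""


class MirsurvError(Exception):
    """Base class for all package errors."""


class ConfigError(MirsurvError):
    """Invalid specification or configuration (bad probabilities, paths, labels)."""


class AlignmentError(MirsurvError):
    """Subject or miRNA identifiers do not line up between inputs."""


class DataError(MirsurvError):
    """Input data violates a precondition (empty matrix, negative raw signal, ...)."""


class DegenerateSampleError(DataError):
    """A sample cannot be normalized (e.g. 75th percentile of zero)."""


class ImputationError(DataError):
    """A site stratum has too few observed normal samples to impute from."""


class StateError(DataError):
    """An expression matrix is in the wrong processing state for an operation."""


class InferenceError(MirsurvError):
    """A model cannot be fit (no events, constant exposure, below expressor floor)."""


class RankError(InferenceError):
    """Design matrix is rank deficient / collinear; no information on a coefficient."""
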