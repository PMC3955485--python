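"""Exception hierarchy for the pipeline.

Every loader/validator failure raises a distinct, named error so callers
(and the CLI) can report precisely which contract was violated.
"""


class PathConsensusError(Exception):
    """Base class for all package errors."""


class LoadError(PathConsensusError):
    """Base class for errors raised while reading external files."""


class DuplicateIDError(LoadError):
    """A probe, sample or pathway identifier occurs more than once."""


class MissingAnnotationError(LoadError):
    """A sample present in the expression matrix has no annotation row."""


class NonNumericValueError(LoadError):
    """An expression-matrix cell is missing or not parseable as a number."""


class UnknownGroupError(LoadError):
    """A sample's group label is neither TUMOR nor NORMAL."""


class GMTParseError(LoadError):
    """A GMT line is malformed (fewer than 3 tab-separated fields)."""


class EmptyDatasetError(PathConsensusError):
    """A filtering step left zero probes; the pipeline cannot proceed."""


class ConfigError(PathConsensusError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidPValueError(PathConsensusError):
    """A probability passed to a combiner is outside (0, 1]."""
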