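"""Exception hierarchy for kinland.

Error classes are deliberately fine-grained so callers (and the CLI) can
distinguish a malformed input file from an empty selection or a degenerate
geometry, which call for different user action.
"""


class KinlandError(Exception):
    """Base class for all package errors."""


class StructureParseError(KinlandError):
    """A coordinate file could not be parsed under the named standard."""


class UnknownFormatError(KinlandError):
    """The requested coordinate format is not recognised."""


class EmptySelectionError(KinlandError):
    """An atom selection matched nothing (distinct from a parse failure)."""


class ConfigurationError(KinlandError):
    """Invalid element-map / spine / pipeline configuration."""


class InsufficientPairingError(KinlandError):
    """Fewer than three residue pairs available for superposition."""


class DegenerateGeometryError(KinlandError):
    """Point sets are degenerate (e.g. collinear) and define no unique rotation."""


class IncompatibleCensusError(KinlandError):
    """Contact censuses computed with different cutoffs cannot be ranked together."""


class AmbiguousLabelError(KinlandError):
    """Duplicate (inhibitor, state) labels in an affinity table."""


class GenerationError(KinlandError):
    """A synthetic-data request is infeasible or invalid."""
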