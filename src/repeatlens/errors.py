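"""Exception hierarchy shared across the package."""


class RepeatLensError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(RepeatLensError):
    """A motif identifier cannot be resolved against the alphabet."""


class StructureError(RepeatLensError):
    """An allele structure violates its own invariants (bad insertion index, ...)."""


class DecompositionError(RepeatLensError):
    """A sequence cannot be tiled into alphabet motifs.

    ``offset`` is the first position at which every tiling attempt failed.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class SequenceError(RepeatLensError):
    """Input is not a plain ACGT DNA string where one is required."""


class DeconvolutionError(RepeatLensError):
    """No candidate allele pair explains a mixed sequence within budget."""

    def __init__(self, message: str, best_partial=None):
        super().__init__(message)
        self.best_partial = best_partial


class ResourceError(RepeatLensError):
    """A bounded search exceeded its configured node budget."""


class ParameterError(RepeatLensError):
    """A numeric parameter is outside its documented range."""


class LDUndefinedError(RepeatLensError):
    """Linkage disequilibrium is undefined (monomorphic locus)."""


class DataError(RepeatLensError):
    """Input data is internally inconsistent (e.g. phase-incompatible genotype)."""


class FitError(RepeatLensError):
    """A model fit cannot proceed (rank-deficient design, ...)."""


class UsageError(RepeatLensError):
    """An operation was called with structurally invalid inputs."""
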