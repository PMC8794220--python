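"""Exception hierarchy for florypot.

All package-specific failures derive from :class:`FlorypotError` so callers
can catch one base class; the finer types mirror the distinct failure modes
of each pipeline stage (parsing, fitting, sampling, orchestration).
"""


class FlorypotError(Exception):
    """Base class for all florypot errors."""


class StructureParseError(FlorypotError):
    """A structure file could not be parsed."""


class EmptyStructureError(FlorypotError):
    """A structure file contained no usable protein residues."""


class MissingAtomError(FlorypotError):
    """A residue lacks the atom(s) required by the coarse-graining level."""


class NoHydrogensError(FlorypotError):
    """HH-level analysis requested on a structure with no hydrogen atoms."""


class InsufficientAtomsError(FlorypotError):
    """Too few atoms to compute a geometric quantity (e.g. R_g)."""


class InsufficientDataError(FlorypotError):
    """Too few samples for a statistical estimate."""


class UnderdeterminedFitError(FlorypotError):
    """A regression has fewer informative points than parameters."""


class IncompleteRangeError(FlorypotError):
    """A per-m quantity is missing for part of a required m range."""


class DomainError(FlorypotError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConsistencyError(FlorypotError):
    """Two objects that must share metadata (m, level) disagree."""


class FitRangeError(FlorypotError):
    """A fit window contains values outside the assumed regime."""


class InsufficientStatisticsError(FlorypotError):
    """A restricted fragment set is too small at every separation."""


class GenerationError(FlorypotError):
    """A synthetic-data generator failed (e.g. rejection-sampling stall)."""


class PipelineStageError(FlorypotError):
    """A pipeline stage failed; the message names the stage."""
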