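"""Exception hierarchy.

Validation errors (bad inputs, malformed specs) are kept distinct from
computation errors (degenerate data encountered mid-analysis) so the CLI can
map them to different exit codes.
"""


class CTCFlowError(Exception):
    """Base class for all package errors."""


class ValidationError(CTCFlowError, ValueError):
    """Invalid input: malformed spec, bad matrix, unknown channel, ..."""


class ComputationError(CTCFlowError, RuntimeError):
    """Well-formed input on which the requested quantity is undefined."""


class DegenerateControlError(ComputationError):
    """Single-stain control whose on-channel signal does not exceed baseline."""


class SingularSpilloverError(ComputationError):
    """Spillover matrix singular or too ill-conditioned to invert."""


class NoCTCsError(ComputationError):
    """A patient summary was requested on an empty CTC set.

    Deliberately distinct from :class:`ValidationError`: zero CTCs is a valid
    biological outcome, not a data-entry mistake.
    """


class UndefinedStatisticError(ComputationError):
    """Statistic undefined on this input (constant vector, no events, ...)."""


class MissingFISHError(ValidationError):
    """IHC 2+ (equivocal) without the FISH ratio needed to resolve it."""


class UnclassifiableError(ValidationError):
    """Tissue-negative patient without CTC status: group B vs C undecidable."""


class FixtureIntegrityError(CTCFlowError):
    """Packaged data file does not match its recorded checksum."""
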