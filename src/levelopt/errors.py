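"""Exception hierarchy shared across the package."""


class LeveloptError(Exception):
    """Base class for all package errors."""


class SchemaError(LeveloptError):
    """An input table is missing a required column or names an unknown field."""


class ValidationError(LeveloptError):
    """A value violates a domain invariant (label set, binary outcome, ...)."""


class ReferentialIntegrityError(ValidationError):
    """A record refers to an identifier absent from the complaint hierarchy."""


class FitError(LeveloptError):
    """A model fit failed; the message carries diagnostics."""


class ConvergenceError(FitError):
    """The optimizer hit its iteration cap before converging."""


class StratificationError(LeveloptError):
    """Cross-validation folds cannot be formed (a class is too rare)."""


class UndefinedAUCError(LeveloptError):
    """AUC requested on a single-class label vector."""


class DegenerateVarianceError(LeveloptError):
    """A variance estimate is zero where a nonzero difference must be tested."""


class SearchSpaceError(LeveloptError):
    """Exhaustive enumeration refused: the mask space exceeds the cap."""
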