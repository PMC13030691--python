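"""Exception hierarchy for petrepeat."""


class PetRepeatError(Exception):
    """Base class for all petrepeat errors."""


class ParameterError(PetRepeatError, ValueError):
    """An invalid parameter value (negative SD, zero patients, ...)."""


class ValidationError(PetRepeatError, ValueError):
    """Input data violates a contract (nonpositive feature, bad schema, ...)."""


class StructuralError(PetRepeatError, ValueError):
    """Structurally inconsistent inputs (shape mismatch between image and mask)."""


class InsufficientDataError(PetRepeatError, ValueError):
    """Too few observations for the requested statistic."""


class PlacementError(PetRepeatError, RuntimeError):
    """Phantom lesion placement failed after bounded retries."""


class ConsistencyError(PetRepeatError, ValueError):
    """Two inputs that must describe the same data disagree."""
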