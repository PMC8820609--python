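"""Exception hierarchy for isomix."""


class IsomixError(Exception):
    """Base class for all isomix errors."""


class InvalidInputError(IsomixError, ValueError):
    """Malformed or out-of-contract input."""


class CoverageError(IsomixError):
    """A forcing input does not cover the requested time span."""


class InvalidTurnoverError(IsomixError):
    """A turnover rate is non-positive somewhere on the simulated span."""


class InsufficientTrajectoriesError(IsomixError):
    """Too few source pairs survive the separation filter.

    Carries the survivor count so callers can decide how to re-parameterise.
    """

    def __init__(self, n_survivors: int, n_keep: int):
        self.n_survivors = n_survivors
        self.n_keep = n_keep
        super().__init__(
            f"only {n_survivors} candidate source pairs satisfy the separation "
            f"filter, but {n_keep} were requested"
        )


class UndefinedMixtureError(IsomixError):
    """The corrected source values coincide, so the mixing line degenerates."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(
            f"corrected source values are equal at t = {time:g} d; "
            "the two-endmember mixture is undefined there"
        )


class WindowTooLongError(IsomixError):
    """The integration window does not fit inside the sampled span."""


class AlignmentError(IsomixError):
    """Reference and estimate do not share a common time grid."""
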