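"""Exception hierarchy shared across the package."""


class LutidoseError(Exception):
    """Base class for all package errors."""


class FormatError(LutidoseError):
    """A file could not be decoded into the expected structure."""


class AlignmentError(LutidoseError):
    """Two lattices do not share shape and spacing."""


class KernelError(LutidoseError):
    """A dose kernel violates its structural contract."""


class QuantityError(LutidoseError):
    """An operation received a grid carrying the wrong physical quantity."""


class UndefinedMetricError(LutidoseError):
    """A contour metric was requested for an empty (or both-empty) mask pair."""


class ConstructionError(LutidoseError):
    """Phantom geometry could not be built (e.g. overlapping organs)."""


class StageError(LutidoseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
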