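"""Exception types shared across the package."""


class GBAError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(GBAError):
    """A model file or bundle is malformed (missing tab, ragged matrix, bad cell)."""

    def __init__(self, message: str, *, tab: str | None = None,
                 row: str | int | None = None, column: str | int | None = None):
        self.tab = tab
        self.row = row
        self.column = column
        super().__init__(message)


class MassConservationError(GBAError):
    """A stoichiometry column violates w.S = 0 (or is all-zero)."""

    def __init__(self, message: str, *, column: str | int | None = None):
        self.column = column
        super().__init__(message)


class InfeasibleModelError(GBAError):
    """The density constraint cannot be met (no net mass import possible)."""
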