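"""Exception hierarchy for mrpforge."""


class MrpForgeError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(MrpForgeError):
    """Malformed Newick input; carries an approximate character offset."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)


class ResolutionError(MrpForgeError):
    """A taxon label could not be resolved through the registry."""


class ValidationError(MrpForgeError):
    """Structurally invalid input data (Q-matrix rows, duplicate leaves, ...)."""


class TaxonMismatchError(MrpForgeError):
    """Operands whose taxon sets were required to match do not."""

    def __init__(self, message: str, only_left=(), only_right=()):
        self.only_left = sorted(only_left)
        self.only_right = sorted(only_right)
        detail = ""
        if self.only_left or self.only_right:
            detail = f" (only in first: {self.only_left}; only in second: {self.only_right})"
        super().__init__(message + detail)


class SearchError(MrpForgeError):
    """Tree-search preconditions violated (too few taxa, size over limits, ...)."""
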