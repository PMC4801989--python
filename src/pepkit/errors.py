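"""Exception hierarchy.

Every user-facing failure raises a :class:`PepkitError` subclass so the CLI
can translate it into a one-line diagnostic without a traceback.
"""


class PepkitError(Exception):
    """Base class for all pepkit errors."""


class FormulaError(PepkitError, ValueError):
    """Malformed molecular-formula string or invalid formula arithmetic.

    ``position`` is the 0-based offset of the offending token when the error
    originates from parsing, else ``None``.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class UnknownElementError(PepkitError, KeyError):
    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown element symbol: {symbol!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return self.args[0]


class UnknownResidueError(PepkitError, KeyError):
    def __init__(self, code: str, polymer_class: str, suggestions: list[str] | None = None):
        self.code = code
        self.polymer_class = polymer_class
        self.suggestions = suggestions or []
        msg = f"unknown {polymer_class} residue code: {code!r}"
        if self.suggestions:
            msg += " (did you mean: " + ", ".join(self.suggestions) + "?)"
        super().__init__(msg)

    def __str__(self) -> str:
        return self.args[0]


class DuplicateResidueError(PepkitError, ValueError):
    pass


class InvalidResidueError(PepkitError, ValueError):
    pass


class SequenceParseError(PepkitError, ValueError):
    """Positioned parse failure; ``position`` is 0-based into the input string."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SequenceLengthError(PepkitError, ValueError):
    pass


class UnknownTerminusError(PepkitError, KeyError):
    def __init__(self, name: str, end: str, available: list[str]):
        self.name = name
        super().__init__(
            f"unknown {end}-terminus {name!r}; available: {', '.join(available)}; "
            "a custom molecular formula string is also accepted"
        )

    def __str__(self) -> str:
        return self.args[0]


class UnsupportedOperationError(PepkitError, TypeError):
    """Operation not defined for this polymer class (e.g. pI of a peptoid)."""


class IsoelectricPointUndefinedError(PepkitError, ValueError):
    """No root of the charge equation exists in (0, 14)."""


class ProfileUnavailableError(PepkitError, ValueError):
    """Strand-contiguity profile requested for a sequence shorter than 10 residues."""


class FragmentUnscorableError(PepkitError, ValueError):
    """Window contains a residue without propensity parameters."""


class StructureUnavailableError(PepkitError, ValueError):
    def __init__(self, code: str):
        self.code = code
        super().__init__(f"no structure template for residue {code!r}; structure unavailable")


class CandidateBudgetExceededError(PepkitError, RuntimeError):
    pass


class InvalidPeakError(PepkitError, ValueError):
    pass
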