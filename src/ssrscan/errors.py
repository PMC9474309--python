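"""Exception hierarchy shared across the package."""


class SsrScanError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(SsrScanError, ValueError):
    """Malformed FASTA input (missing header, empty record, bad residue)."""


class SequenceAlphabetError(FastaFormatError):
    """A residue outside {A, C, G, T, N} (after case folding and U->T)."""

    def __init__(self, character: str, position: int, context: str = ""):
        self.character = character
        self.position = position
        where = f" in {context}" if context else ""
        super().__init__(
            f"disallowed character {character!r} at position {position}{where}"
        )


class DegenerateDataError(SsrScanError, ValueError):
    """Zero within-group variance: the F denominator is undefined."""


class UnbalancedDesignError(SsrScanError, ValueError):
    """Two-way layout with unequal replicate counts per cell."""


class RetryLimitError(SsrScanError, RuntimeError):
    """A bounded stochastic-repair loop exhausted its retry budget."""
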