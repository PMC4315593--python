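"""Exception hierarchy.

Every data-level failure raises a subclass of :class:`FinidError`; the CLI
maps these to exit code 1 and usage problems to exit code 2.
"""


class FinidError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(FinidError):
    """A character outside the IUPAC nucleotide alphabet."""


class FastaParseError(FinidError):
    """Malformed FASTA input (empty record, duplicate id, ...)."""


class CoordinateError(FinidError):
    """A COI position outside the registered coordinate range."""


class InputError(FinidError):
    """Structurally invalid input to an operation."""


class TrimError(FinidError):
    """Amplicon insert does not overlap the requested readable region."""


class InseparableTaxaError(FinidError):
    """A relative cannot be separated from the target at any candidate position."""

    def __init__(self, target: str, relative: str):
        self.target = target
        self.relative = relative
        super().__init__(
            f"no candidate position separates {relative!r} from target {target!r}"
        )


class KeyDegeneracyError(FinidError):
    """Two key rows are compatible at every position (not pairwise diagnostic)."""


class KeyLookupError(FinidError):
    """A species absent from the key rows."""


class NoInformationError(FinidError):
    """Query covers zero key positions."""


class ConfigError(FinidError):
    """Invalid simulation or run configuration."""
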