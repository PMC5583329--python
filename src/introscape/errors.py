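"""Exception hierarchy shared across the package."""


class IntroscapeError(Exception):
    """Base class for all package errors."""


class InputError(IntroscapeError):
    """Malformed or inconsistent user input (exit code 2 in the CLI)."""


class StructuralError(InputError):
    """A gene model violates structural constraints (overlapping CDS, zero-length intron)."""


class DomainError(IntroscapeError):
    """An operation was called outside its mathematical domain."""


class ConsistencyError(IntroscapeError):
    """Cross-input disagreement, e.g. CDS translation does not match the alignment row."""
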