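"""Exception hierarchy shared across the package."""


class R3DFoldError(Exception):
    """Base class for all package errors."""


class FormatError(R3DFoldError):
    """Malformed input file (alignment, pair list, descriptor, grammar)."""


class ContractError(R3DFoldError):
    """A documented precondition was violated by the caller."""


class NoStructureError(R3DFoldError):
    """No finite-probability parse exists under the given constraints."""
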