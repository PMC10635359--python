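"""Exception types shared across the package."""


class PFPFMError(Exception):
    """Base class for all package-specific errors."""


class InputError(PFPFMError):
    """Malformed or invalid user input (text, FASTA, patterns, parameters)."""


class CorruptionError(PFPFMError):
    """Inconsistent serialized data or an internally inconsistent structure."""


class ContractError(PFPFMError):
    """A caller violated an operation's precondition (indicates a caller bug)."""
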