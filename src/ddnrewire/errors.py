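"""Exception hierarchy shared across the package."""


class DDNRewireError(Exception):
    """Base class for all package errors."""


class FormatError(DDNRewireError, ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(DDNRewireError, ValueError):
    """Inputs parse but violate a documented invariant or precondition."""


class ContractError(DDNRewireError, ValueError):
    """Two in-memory objects that must agree (e.g. candidate pair sets) do not."""
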