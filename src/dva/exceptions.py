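"""Exception hierarchy shared across the pipeline stages."""


class DVAError(Exception):
    """Base class for all package errors."""


class SchemaError(DVAError):
    """A required column or feature-schema entry is missing or mis-sized."""


class ParameterError(DVAError):
    """A user-supplied parameter is outside its valid range."""


class ContractError(DVAError):
    """Caller violated an interface contract (mis-aligned inputs, bad state)."""


class ConflictError(DVAError):
    """Equal-priority sources carry the same variant key with different labels."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"conflicting labels at equal priority for keys: {self.keys}")


class FormatError(DVAError):
    """An input file violates its declared dialect."""


class EmptyGraphError(DVAError):
    """No edges survive thresholding; the PPI graph would be empty."""


class DeadEndError(DVAError):
    """A step distribution was requested at a node with no neighbors."""


class StratificationError(DVAError):
    """A cross-validation training split contains a single class."""


class FingerprintError(DVAError):
    """A persisted model's config fingerprint does not match the request."""
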