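"""Exception hierarchy shared across the pipeline."""


class PatchvoteError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(PatchvoteError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(PatchvoteError):
    """Input is structurally valid but carries too little information
    for the operation (e.g. no tissue pixels, rank-deficient stain cloud)."""


class InvalidDataError(PatchvoteError):
    """Data records violate a contract (missing class, mixed image ids, ...)."""
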