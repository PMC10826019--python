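"""Exception hierarchy shared across the package."""


class PlaquehubError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlaquehubError):
    """A file violated its expected on-disk format or an invariant."""


class ParameterError(PlaquehubError, ValueError):
    """A function argument is outside its documented domain."""


class InputError(PlaquehubError, ValueError):
    """Input data are structurally valid but unusable for the operation."""
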