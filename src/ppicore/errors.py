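"""Exception types shared across the package."""


class PpicoreError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PpicoreError):
    """An input file is missing a required column or is malformed."""


class EmptyInputError(PpicoreError):
    """An input file or table contained no usable rows."""


class EmptyNetworkError(PpicoreError):
    """A network construction or restriction produced zero edges/nodes."""
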