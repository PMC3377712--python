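"""Exception hierarchy.

The CLI maps these onto exit codes: configuration/parameter problems exit
with 2, data/format problems with 3.
"""


class VaginomeError(Exception):
    """Base class for all package errors."""


class ParameterError(VaginomeError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(VaginomeError, ValueError):
    """An invalid configuration (barcode maps, pipeline config, ...)."""


class DataError(VaginomeError, ValueError):
    """Input data violates a documented invariant."""


class FormatError(DataError):
    """A file does not conform to its format (jplace, newick, ...)."""
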