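"""Exception hierarchy.

``EcompassError`` is the base for every error the pipeline raises on bad
input or unusable data; the CLI maps it to exit code 2 (data error), while
argument/usage problems exit with code 1.
"""


class EcompassError(Exception):
    """Base class for all package errors."""


class FormatError(EcompassError):
    """A file does not parse in its declared format."""


class ConfigError(EcompassError):
    """A configuration value is outside its documented range."""


class DataError(EcompassError):
    """Input data are structurally valid but unusable for the analysis."""
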