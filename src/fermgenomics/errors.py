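"""Exception hierarchy shared across the pipeline."""


class FermgenomicsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FermgenomicsError):
    """A file does not conform to the expected tabular/sequence format."""


class ParseError(FermgenomicsError):
    """A cell or field could not be parsed; the message names the row."""


class ValidationError(FermgenomicsError):
    """Input violates a documented invariant or precondition."""


class ConfigError(FermgenomicsError):
    """A configuration value is out of its allowed range."""


class DependencyError(FermgenomicsError):
    """A pipeline stage was run before the outputs it depends on exist."""


class ChecksumError(FermgenomicsError):
    """A recorded checksum does not match the file on disk."""
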