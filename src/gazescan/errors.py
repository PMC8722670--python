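"""Exception hierarchy shared across the package."""


class GazeScanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazeScanError):
    """A file could not be parsed as the expected format."""


class DataError(GazeScanError):
    """Parsed data violates an invariant (e.g. non-monotone timestamps)."""


class ManifestError(GazeScanError):
    """A cohort manifest is internally inconsistent."""


class ConfigError(GazeScanError):
    """A configuration object is invalid or internally inconsistent."""
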