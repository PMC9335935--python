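"""Exception hierarchy shared across the package.

Exit-code policy for the CLI: configuration problems map to exit code 2,
malformed or inconsistent data to exit code 3.
"""


class SdrkitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(SdrkitError):
    """Invalid or inconsistent configuration (missing samples, bad thresholds)."""

    exit_code = 2


class DataFormatError(SdrkitError):
    """Malformed input data (VCF without GT, inconsistent matrices)."""

    exit_code = 3
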