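"""Typed error hierarchy.

Every malformed input raises one of these; nothing is silently dropped.
CLI maps ValidationError/SchemaError to exit code 2 and
ConfigurationError to exit code 3.
"""


class EquicatchError(Exception):
    """Base class for all package errors."""


class SchemaError(EquicatchError):
    """An input table is missing a required column or has the wrong shape."""


class ValidationError(EquicatchError):
    """A value violates a domain invariant (names the offending record)."""


class ConfigurationError(EquicatchError):
    """The requested run is impossible with the supplied configuration."""
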