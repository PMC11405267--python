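"""Exception hierarchy.

Data problems (malformed records, mixed patients, missing annotations) raise
:class:`DataError`; invalid configuration raises :class:`ConfigError`.  The CLI
maps these to exit codes 1 and 2 respectively.
"""


class CtdnaError(Exception):
    """Base class for all package errors."""


class DataError(CtdnaError):
    """Input data violates a documented contract."""


class ConfigError(CtdnaError):
    """Configuration is missing, malformed or out of range."""
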