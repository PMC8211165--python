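"""Exception hierarchy shared across the package."""


class GroupBanditError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GroupBanditError, ValueError):
    """Invalid task, prior, or run configuration."""


class DataError(GroupBanditError, ValueError):
    """Malformed or inconsistent behavioral data."""


class DesignError(GroupBanditError, ValueError):
    """Invalid synthetic-dataset design (counts, rosters, coherence)."""


class FitError(GroupBanditError, RuntimeError):
    """Parameter estimation failed on every attempt."""
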