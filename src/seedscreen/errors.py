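"""Exception hierarchy for seedscreen.

All library errors derive from :class:`SeedScreenError` so callers can catch
one base class; the leaf classes distinguish malformed input files from
statistically degenerate data and from invalid run configuration.
"""


class SeedScreenError(Exception):
    """Base class for all seedscreen errors."""


class FormatError(SeedScreenError):
    """A file violates the expected tabular format (duplicate ids, bad cells)."""


class DomainError(SeedScreenError):
    """Input values violate a domain constraint (negative time, no pairs...)."""


class ConstantFeatureError(DomainError):
    """A regression feature has zero variance on the complete-pair subset."""


class InsufficientSamplesError(DomainError):
    """Fewer complete sample pairs than the minimum the statistic needs."""


class KeyNotFoundError(SeedScreenError):
    """A requested feature or sample id is absent from the container."""


class ConfigurationError(SeedScreenError):
    """A run/tier/generator configuration is internally inconsistent."""
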