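"""Exception hierarchy for nemaquant."""


class NemaquantError(Exception):
    """Base class for all nemaquant errors."""


class InvalidConfigError(NemaquantError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class NormalizationError(NemaquantError, ValueError):
    """A frame pair has zero mean intensity; the difference image cannot be normalized."""


class InsufficientDataError(NemaquantError, ValueError):
    """Too little data to run the requested analysis (e.g. too few nonzero histogram bins)."""


class DegenerateFitError(NemaquantError, ValueError):
    """A mixture fit has zero total area; no dwelling fraction is defined."""


class InvalidMidlineError(NemaquantError, ValueError):
    """A worm midline is degenerate (too few points, duplicate consecutive points, zero length)."""


class DegenerateProfileError(NemaquantError, ZeroDivisionError):
    """A free-locomotion amplitude profile is zero where a ratio is required."""


class SchemaError(NemaquantError, ValueError):
    """An interchange file does not conform to its documented column schema."""
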