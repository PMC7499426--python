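"""Exception types shared across the pipeline stages."""


class LarvaswimError(Exception):
    """Base class for all package errors."""


class ConfigError(LarvaswimError, ValueError):
    """Invalid configuration (non-positive counts, negative dispersions...)."""


class GenerationError(LarvaswimError):
    """The requested synthetic recording cannot be generated (e.g. the
    bout density leaves no room for inter-bout glides)."""


class TrackingError(LarvaswimError):
    """Unrecoverable tracking problem (per-frame failures are flagged,
    not raised)."""


class SessionRejected(LarvaswimError):
    """Too many flagged frames in a session for bout detection to be
    trustworthy."""


class ComparisonError(LarvaswimError):
    """Group comparison cannot be carried out (missing genotype, constant
    parameter column...)."""
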