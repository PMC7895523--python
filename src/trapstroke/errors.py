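"""Exception hierarchy shared across the package."""


class TrapstrokeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrapstrokeError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(TrapstrokeError, ValueError):
    """Malformed trace/event/config file."""


class AnalysisError(TrapstrokeError, RuntimeError):
    """An analysis step failed (non-convergence, degenerate input, ...)."""


class MoleculeNotAnalyzableError(AnalysisError):
    """Bound/unbound covariance peaks are not separated; the molecule is
    excluded from analysis rather than force-fit."""
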