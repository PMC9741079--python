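"""Exception hierarchy shared across the package."""


class TunnelMetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(TunnelMetricsError, ValueError):
    """An object or argument violates a documented invariant."""


class ParseError(TunnelMetricsError, ValueError):
    """An input file does not conform to the documented dialect."""


class TraceError(TunnelMetricsError, RuntimeError):
    """Channel tracing failed (occluded start or no path to the exterior)."""
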