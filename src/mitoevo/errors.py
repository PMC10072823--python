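"""Exception types raised across the package."""


class MitoevoError(Exception):
    """Base class for package errors."""


class ConfigurationError(MitoevoError, ValueError):
    """Invalid configuration (bad rates, empty catalogs, missing seeds...)."""


class DegenerateCurveError(MitoevoError, ValueError):
    """Growth curve is flat, empty or monotone-decreasing: unfittable."""


class InsufficientSeriesError(MitoevoError, ValueError):
    """Competition series has fewer than 3 usable timepoints."""


class CoordinateMismatchError(MitoevoError, ValueError):
    """Two per-position tables do not share coordinates."""


class TableFormatError(MitoevoError, ValueError):
    """A table file does not parse under the declared dialect."""
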