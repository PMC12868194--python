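"""Exception hierarchy shared across the pipeline stages."""


class EratrendError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EratrendError, ValueError):
    """A configuration value violates its invariants."""


class PedigreeError(EratrendError, ValueError):
    """Structural problem in a pedigree (cycles, duplicate ids, ...)."""


class SchemaError(EratrendError, ValueError):
    """An input table is missing required columns or has bad types."""


class ConvergenceError(EratrendError, RuntimeError):
    """A REML fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None, diagnostics=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.diagnostics = diagnostics or {}


class ConnectivityError(EratrendError, ValueError):
    """The genotype-by-environment table is disconnected; names components."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class DegenerateDataError(EratrendError, ValueError):
    """Data degenerate for the requested analysis (constant regressor, ...)."""


class NoTrialsRetainedError(EratrendError, RuntimeError):
    """Quality-control filtering removed every trial."""
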