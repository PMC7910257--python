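"""Exception hierarchy.

``ConfigurationError`` marks invalid user input (CLI exit code 1); the
remaining classes mark failures inside a pipeline stage (exit code 2).
"""


class HpdhacError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HpdhacError):
    """Invalid or inconsistent user configuration."""


class DesignError(HpdhacError):
    """Pulse design cannot satisfy the requested specification."""


class SimulationError(HpdhacError):
    """Numerical failure inside the kinetic or Bloch simulator."""


class ProcessingError(HpdhacError):
    """Spectral processing / quantification failure."""
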