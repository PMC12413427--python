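"""Exception types used across the package."""


class MlmvarError(Exception):
    """Base class for package errors."""


class ConfigurationError(MlmvarError):
    """Invalid model specification or generating configuration."""


class SimulationError(MlmvarError):
    """Data generation failed (e.g., non-finite trajectory)."""


class EstimationError(MlmvarError):
    """Posterior sampling could not be run or initialized."""


class PanelFormatError(MlmvarError):
    """Malformed long-format panel input."""
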