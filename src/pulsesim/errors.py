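"""Exception hierarchy for pulsesim.

All failure modes raise a subclass of :class:`PulseSimError` so that the CLI
can map any library failure to a nonzero exit code with a single handler.
"""


class PulseSimError(Exception):
    """Base class for all pulsesim errors."""


class ConfigurationError(PulseSimError):
    """A simulator setting violates its physical or numerical constraints."""


class ChamberSaturationError(PulseSimError):
    """The fluid displaced into the compliance chamber reached the gas volume."""


class NumericalDivergenceError(PulseSimError):
    """The loop integration produced a non-finite state."""


class BufferUnderrunError(PulseSimError):
    """The forward-wave history does not reach back far enough for the delay."""


class FeatureAbsentError(PulseSimError):
    """A fiducial point could not be located on the waveform."""

    def __init__(self, feature: str, message: str | None = None):
        self.feature = feature
        super().__init__(message or f"waveform feature not found: {feature}")


class UndefinedIndexError(PulseSimError):
    """An index (e.g. augmentation index) is undefined for the given features."""


class CalibrationError(PulseSimError):
    """The calibration optimiser failed to reach the target tolerance."""

    def __init__(self, message: str, best_residual: float | None = None):
        self.best_residual = best_residual
        super().__init__(message)


class WaveformFormatError(PulseSimError):
    """A waveform file does not conform to the CSV contract."""


class InputError(PulseSimError):
    """Invalid input data (non-uniform sampling, empty record, grid mismatch)."""
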