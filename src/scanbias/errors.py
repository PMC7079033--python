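"""Exception hierarchy for the scanbias pipeline."""


class ScanBiasError(Exception):
    """Base class for all scanbias errors."""


class ConfigurationError(ScanBiasError):
    """A growth-standard or run configuration is missing or inconsistent."""


class NumericalError(ScanBiasError):
    """A numerical routine (curve inversion) failed to converge or bracket."""


class DataError(ScanBiasError):
    """Input data violate a structural precondition (empty trajectory, bad log)."""


class InputError(ScanBiasError):
    """A raw input stream violates its contract (e.g. unsorted gaze samples)."""
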