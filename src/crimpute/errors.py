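"""Exception hierarchy for grouped-time competing-risks data handling."""


class CrimputeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrimputeError):
    """Invalid configuration, e.g. a missing required column mapping."""


class FormatError(CrimputeError):
    """Malformed input, e.g. non-integer or zero observed times."""


class DataError(CrimputeError):
    """Invalid cell content, e.g. a missing value; names the offending row."""


class DegenerateGridError(CrimputeError):
    """Too few distinct times to build the requested number of intervals."""


class DegenerateWeightError(CrimputeError):
    """No censoring mass left after an individual's observed time, so no
    later censoring time is estimable for them."""


class GridMismatchError(CrimputeError):
    """Two objects that must share a time grid do not."""


class TrainingError(CrimputeError):
    """Non-finite loss or other optimizer failure."""
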