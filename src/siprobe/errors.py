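"""Exception hierarchy shared across the package."""


class SiprobeError(Exception):
    """Base class for all package-specific errors."""


class TranscriptError(SiprobeError, ValueError):
    """Malformed or inconsistent time-coded transcript data."""


class ConfigurationError(SiprobeError, ValueError):
    """Invalid or incomplete configuration (unknown language, missing table, ...)."""


class AlignmentError(SiprobeError, ValueError):
    """Source/target alignment ids are inconsistent."""


class DegenerateTableError(SiprobeError, ValueError):
    """Frequency table with F_min == F_max; Eq.-style min-max scaling undefined."""


class InsufficientDataError(SiprobeError, ValueError):
    """Not enough observations for the requested statistic."""
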