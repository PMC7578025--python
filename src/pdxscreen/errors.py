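"""Exception hierarchy shared across the pipeline."""


class PdxScreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PdxScreenError):
    """Invalid configuration (bad counts, fractions out of range, ...)."""


class CapacityError(ConfigError):
    """Requested wells exceed available plate capacity."""


class PlateFormatError(PdxScreenError):
    """Malformed plate table (bad well id, duplicate well, negative RLU)."""


class QCFatalError(PdxScreenError):
    """Plate cannot be processed at all (e.g. no vehicle wells)."""


class DegeneratePlateError(PdxScreenError):
    """Plate whose controls make normalization undefined (median DMSO = 0)."""


class InsufficientDataError(PdxScreenError):
    """Not enough observations for the requested computation."""
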