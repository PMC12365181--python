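"""Exception hierarchy shared across the package."""


class LcsodError(Exception):
    """Base class for all package errors."""


class FormatError(LcsodError):
    """Malformed input file (bad JSON, missing COCO keys, ...)."""


class IntegrityError(LcsodError):
    """Referential-integrity violation in a dataset (dangling ids, duplicates)."""


class DegenerateBoxError(LcsodError, ValueError):
    """A bounding box with non-positive width or height."""


class ConfigurationError(LcsodError, ValueError):
    """Invalid configuration value or inconsistent shapes."""


class ValidationError(LcsodError, ValueError):
    """Invalid runtime input (NaN costs, unknown category, ...)."""
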