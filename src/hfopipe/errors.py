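"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`HfoPipeError`, so callers (and the
CLI) can catch one type and still report the offending stage precisely.
"""


class HfoPipeError(Exception):
    """Base class for all errors raised by hfopipe."""


class ConfigurationError(HfoPipeError, ValueError):
    """An invalid configuration value; message names the offending field."""


class FormatError(HfoPipeError, ValueError):
    """A file could not be parsed as the expected on-disk format."""


class DegenerateWindowError(HfoPipeError, ValueError):
    """A feature was requested on a window shorter than its definition allows."""


class DegenerateEventError(HfoPipeError, ValueError):
    """An event too short to contain the minimum number of oscillation cycles."""


class InfeasibleRateError(HfoPipeError, RuntimeError):
    """Event rejection sampling failed repeatedly; the requested rate is too high."""


class ImbalanceError(HfoPipeError, ValueError):
    """Class counts make the requested balancing impossible."""


class StratificationError(HfoPipeError, ValueError):
    """A stratified split or fold cannot be formed with the available counts."""


class SizeError(HfoPipeError, ValueError):
    """A requested sample or matrix size is out of range."""


class ModelCompatibilityError(HfoPipeError, ValueError):
    """A trained model was applied to data with a mismatching schema."""


class FeasibilityError(HfoPipeError, ValueError):
    """A requested procedure is combinatorially infeasible at this size."""
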