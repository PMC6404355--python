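"""Exception hierarchy for hepazone."""


class HepazoneError(Exception):
    """Base class for all hepazone errors."""


class InvalidParameterError(HepazoneError, ValueError):
    """A parameter or input violates a documented precondition."""


class UndefinedMetricError(HepazoneError):
    """A metric is undefined for the given input (e.g. flat profile)."""


class BracketError(HepazoneError):
    """A root-finding bracket does not contain the target value."""
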