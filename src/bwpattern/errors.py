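"""Exception hierarchy for bwpattern."""


class BwpatternError(Exception):
    """Base class for all bwpattern errors."""


class ParameterError(BwpatternError, ValueError):
    """An argument is outside its valid domain or inconsistent with the input."""


class InputFormatError(BwpatternError, ValueError):
    """A file could not be decoded as an image or matrix."""


class UndefinedMetricError(BwpatternError, ValueError):
    """The requested metric is mathematically undefined on this input
    (e.g. denseness of an all-transparent matrix, crest height with no
    black pixel)."""
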