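"""Exception hierarchy shared across the pipeline."""


class PPGDistortError(Exception):
    """Base class for all package errors."""


class ParameterError(PPGDistortError, ValueError):
    """Invalid argument value (non-positive width, empty signal, ...)."""


class DesignError(PPGDistortError):
    """A digital filter could not be realized as requested."""


class NoBeatError(PPGDistortError):
    """No cardiac beat could be detected in the signal."""


class UndefinedIndexError(PPGDistortError):
    """A morphology index is undefined for the given input (e.g. zero
    variance for the skewness index, or no eligible beats for RI/ETc)."""


class DegenerateTestError(PPGDistortError):
    """A statistical test has no information to work with (all paired
    differences are zero)."""
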