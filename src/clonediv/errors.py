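"""Exception hierarchy shared across the pipeline stages."""


class CloneDivError(Exception):
    """Base class for all package errors."""


class InputError(CloneDivError, ValueError):
    """Malformed or inconsistent user input (labels, metadata, duplicates)."""


class AlignmentError(InputError):
    """Sequences that do not form a valid alignment (ragged rows, bad characters)."""


class UndefinedStatisticError(CloneDivError, ValueError):
    """A statistic requested on an input where it is mathematically undefined (e.g. n < 2)."""


class AnalysisError(CloneDivError, ValueError):
    """An analysis precondition violated (e.g. an AMOVA group with fewer than 2 sequences)."""


class NoTestError(CloneDivError):
    """The data do not admit the requested test (distinct from a test returning p = 1)."""


class LogicError(CloneDivError, RuntimeError):
    """Internal invariant violated; indicates a pipeline bug, not bad input."""


class ParameterError(CloneDivError, ValueError):
    """Invalid simulation or model parameters."""


class PipelineError(CloneDivError, RuntimeError):
    """A pipeline stage could not produce usable output (e.g. empty dataset after filtering)."""
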