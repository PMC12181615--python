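"""Exception hierarchy shared across the pipeline stages."""


class CmhqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CmhqError, ValueError):
    """A parameter or configuration field is invalid; the message names it."""


class DegenerateInputError(CmhqError, ValueError):
    """An input is too degenerate for the operation (e.g. constant image)."""


class DataError(CmhqError, ValueError):
    """Input data violates a structural contract (codes, ids, shapes)."""


class StatisticsError(CmhqError, ValueError):
    """Not enough groups/observations for the requested statistical test."""
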