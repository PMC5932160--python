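"""Exception hierarchy shared across the pipeline stages."""


class QtapError(Exception):
    """Base class for all qtap errors."""


class FormatError(QtapError):
    """Malformed input table (missing column, duplicate identifier, ...)."""


class BaitNotFoundError(QtapError):
    """No protein-group row matches the designated bait identifier."""


class ConfigError(QtapError):
    """Invalid or inconsistent configuration."""


class ImputationError(QtapError):
    """An imputation scope cannot supply the statistics the draw needs."""


class PermutationError(QtapError):
    """The design does not admit the requested permutation scheme."""


class StatisticError(QtapError):
    """A test statistic is undefined for the given inputs."""
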