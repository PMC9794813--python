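class MECellError(Exception):
    """Base class for package errors."""


class ConfigurationError(MECellError):
    """Contradictory or invalid generator / run configuration."""


class BuildError(MECellError):
    """Model assembly failed (missing role, invalid sequence, ...)."""


class SolveError(MECellError):
    """LP solve failed for a reason other than plain infeasibility."""


class ContractError(MECellError):
    """An operation was called outside its contract."""
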