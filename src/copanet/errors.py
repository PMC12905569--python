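"""Exception and warning types shared across the pipeline."""


class CopanetError(Exception):
    """Base class for all package errors."""


class ConfigError(CopanetError):
    """A configuration field is invalid; the message names the field."""


class EmptyInputError(CopanetError):
    """An input table contained no usable rows."""


class EmptyGraphError(CopanetError):
    """The user-disorder bipartite graph has no edges."""


class UndefinedMetricError(CopanetError):
    """A metric is undefined for the given input (e.g. empty user set)."""


class NodeSetMismatchError(CopanetError):
    """Two partitions or networks do not share the required node set."""


class StageError(CopanetError):
    """A pipeline stage failed; carries a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


class DegenerateNullWarning(UserWarning):
    """Null standard deviation is zero but the observed value deviates."""


class RigidGraphWarning(UserWarning):
    """No successful edge swap was possible; the input graph was returned."""
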