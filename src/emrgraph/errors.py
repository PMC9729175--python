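"""Exception hierarchy shared across the package."""


class EmrGraphError(Exception):
    """Base class for all package errors."""


class ConfigError(EmrGraphError):
    """Invalid configuration (bad fractions, inverted date windows, ...)."""


class ConsistencyError(EmrGraphError):
    """Data violates an invariant that upstream stages should have enforced."""


class SchemaError(EmrGraphError):
    """A feature schema references columns that do not exist."""


class QueryError(EmrGraphError):
    """A graph query references an unknown predicate or property."""


class PatientNotFoundError(EmrGraphError):
    """Requested patient is absent from the graph."""


class CypherParseError(EmrGraphError):
    """A Cypher export script contains a statement outside the emitted dialect."""


class MetricError(EmrGraphError):
    """A metric is undefined for the given labels (e.g. single-class AUROC)."""
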