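"""Exception hierarchy shared across the pipeline stages.

The CLI maps these onto exit codes: input problems (2), modeling problems (3),
aggregation problems (4).
"""


class GSMError(Exception):
    """Base class for all package errors."""


class InputError(GSMError, ValueError):
    """Malformed or inconsistent input data (tables, labels, clade strings)."""


class ModelingError(GSMError, ValueError):
    """Errors raised while scoring groups or fitting/evaluating models."""


class AggregationError(GSMError, ValueError):
    """Errors raised during rank aggregation or significance propagation."""
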