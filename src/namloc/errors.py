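"""Exception hierarchy for the classification framework."""


class NamlocError(Exception):
    """Base class for all framework errors."""


class SchemaError(NamlocError):
    """A required column or key is missing from an input table."""


class ValidationError(NamlocError):
    """A value violates a domain invariant (units, ranges, vocabularies)."""


class ConfigError(NamlocError):
    """The configuration violates an invariant (e.g. inverted cutoffs)."""


class InsufficientInputError(NamlocError):
    """Not enough evidence to run an assessment step.

    Callers must treat this as "not assessable", never as a Low outcome:
    the framework's exclusion principle forbids absence of data from
    lowering concern.
    """


class UnsupportedRouteError(NamlocError):
    """A dosing route other than oral was requested."""
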