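"""Exception hierarchy.

Validation problems (bad user input, bad config) and runtime/fit failures are
kept distinct so the CLI can map them to exit codes 1 and 2 respectively.
"""


class ValidationError(ValueError):
    """Input violates a precondition (geometry, units, ranges, schema)."""


class ConfigurationError(ValidationError):
    """Session/config file is structurally invalid or incomplete."""


class DegenerateDataError(ValidationError):
    """Data carry no information for the requested fit (flat, <2 distinct x)."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge."""
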