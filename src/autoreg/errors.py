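"""Exception types shared across the toolkit."""


class ValidationError(ValueError):
    """Raised when an input value or configuration field is invalid."""


class NotObtainable(Exception):
    """Raised (or carried as a value) when a metric cannot be computed.

    Mirrors the clinical situation in which a recording yields no reliable
    index (too few valid windows, no valid compression episodes) — this is a
    reportable outcome, not a programming error.
    """
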