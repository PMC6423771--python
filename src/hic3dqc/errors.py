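"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class UndefinedScoreError(ValueError):
    """A score is undefined for the given inputs (e.g. everything filtered).

    Raised instead of silently returning a number so callers can decide
    how to aggregate (the benchmark layer drops undefined chromosomes
    with a warning).
    """
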