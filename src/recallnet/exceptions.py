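"""Exception hierarchy for recallnet."""


class RecallnetError(Exception):
    """Base class for all recallnet errors."""


class InvalidNetworkError(RecallnetError, ValueError):
    """A network violates a structural precondition (e.g. fewer than two nodes)."""


class ParseError(RecallnetError, ValueError):
    """A signed edge-list file is malformed; the message names the line number."""


class GenerationError(RecallnetError, RuntimeError):
    """Fixture generation could not satisfy a constraint; the message names it."""


class UndefinedProbabilityError(RecallnetError, ValueError):
    """A model probability is undefined for the given target (degenerate census)."""
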