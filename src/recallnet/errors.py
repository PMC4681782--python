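"""Exception hierarchy for recallnet."""


class RecallNetError(Exception):
    """Base class for all recallnet errors."""


class ParameterError(RecallNetError, ValueError):
    """A parameter is outside its admissible range."""


class DegeneracyError(RecallNetError):
    """A degenerate configuration (e.g. an empty memory representation)."""


class SizeError(RecallNetError):
    """A problem size exceeds a guard intended to protect memory/runtime."""


class DivergenceError(RecallNetError):
    """The integrated state became non-finite or unboundedly large."""


class StabilityError(RecallNetError):
    """The integration step is too large for the membrane time constant."""


class SimultaneityError(RecallNetError):
    """Two memories were above the recall threshold at the same sample."""
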