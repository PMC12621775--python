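"""Exception hierarchy for snarlmap."""


class SnarlmapError(Exception):
    """Base class for all snarlmap errors."""


class GFAParseError(SnarlmapError):
    """Malformed or unsupported GFA input.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UnsupportedDialectError(GFAParseError):
    """GFA feature outside the supported dialect (e.g. non-trivial overlaps)."""


class BrokenWalkError(SnarlmapError):
    """A walk step pair is not joined by an edge; carries the step index."""

    def __init__(self, message, step_index=None):
        self.step_index = step_index
        super().__init__(message)


class BoundsError(SnarlmapError):
    """Position offset outside its node, or similar out-of-range access."""


class InvalidPairError(SnarlmapError):
    """Boundary-pair query with both sides on the same node."""


class ConsistencyError(SnarlmapError):
    """Mismatched graph/tree/index objects passed together."""


class ParameterError(SnarlmapError):
    """Invalid parameter value (e.g. k > 31, empty haplotype set)."""


class GenerationError(SnarlmapError):
    """Synthetic-graph parameters cannot be satisfied (e.g. too many events)."""


class EvaluationError(SnarlmapError):
    """Mapping evaluation input mismatch (e.g. read missing from truth set)."""
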