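"""Exception hierarchy for fluximba."""


class FluximbaError(Exception):
    """Base class for all fluximba errors."""


class FormatError(FluximbaError):
    """A model/data file could not be parsed in its declared dialect."""


class ValidationError(FluximbaError):
    """A model or dataset violates a structural invariant."""


class GprParseError(FormatError):
    """A gene-protein-reaction rule is not a valid Boolean expression."""


class SolverError(FluximbaError):
    """An LP solve did not return the status required by the caller."""


class InfeasibleProblemError(SolverError):
    """The LP is infeasible (e.g. a lethal knockout under a growth demand)."""

    def __init__(self, message: str, lethal: bool = False):
        super().__init__(message)
        self.lethal = lethal


class RmfUnreachableError(FluximbaError):
    """The required metabolic functionality has zero maximum flux."""
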