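"""Exception hierarchy shared across norcad.

Each class maps to a distinct CLI exit code so shell pipelines can tell
malformed input from infeasible design instances from solver failures.
"""


class NorcadError(Exception):
    """Base class for all norcad errors."""

    exit_code = 1


class FormatError(NorcadError):
    """A file could not be parsed (names the offending line/field)."""

    exit_code = 2


class ValidationError(NorcadError):
    """A parsed object violates a domain invariant."""

    exit_code = 2


class StructuralError(NorcadError):
    """A netlist is malformed: cycle, bad arity, unreachable node."""

    exit_code = 2


class AssignmentError(NorcadError):
    """An assignment is incomplete or references unknown gates."""

    exit_code = 2


class ScheduleError(NorcadError):
    """An inducer schedule has gaps, overlaps, or a nonzero start."""

    exit_code = 2


class DataError(NorcadError):
    """A dataset is too small or degenerate for the requested fit."""

    exit_code = 2


class SpecificationError(NorcadError):
    """A truth-table specification is unusable (e.g. no ON or no OFF rows)."""

    exit_code = 2


class CapacityError(NorcadError):
    """The instance cannot be realized within the stated resource bound."""

    exit_code = 3


class NumericalError(NorcadError):
    """An iterative solver failed to converge."""

    exit_code = 4
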