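"""Typed exception hierarchy.

Every failure mode that a caller may want to branch on gets its own class;
silent sentinels (NaN descriptors, empty results) are never returned.
"""

from __future__ import annotations


class NumstimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NumstimError, ValueError):
    """A structurally invalid argument (non-positive size, empty list, ...)."""


class UndefinedDescriptorError(NumstimError):
    """A descriptor that does not exist for the given configuration.

    Inter-distance and density are undefined for a single element.
    """


class InfeasibleCombinationError(NumstimError):
    """Jointly requested variables that geometry cannot satisfy (e.g. TA+TP)."""

    def __init__(self, message: str, offending: tuple[str, ...] = ()):
        super().__init__(message)
        self.offending = offending


class MissingParameterError(NumstimError):
    """A required field of a constraint specification is absent."""


class InfeasibleGeometryError(NumstimError):
    """A target value that exceeds what the arena geometry allows."""


class BudgetExhaustedError(NumstimError):
    """Rejection sampling ran out of attempts; carries the best candidate."""

    def __init__(self, message: str, best=None, best_error: float | None = None):
        super().__init__(message)
        self.best = best
        self.best_error = best_error


class PinsExceedTargetError(NumstimError):
    """Pinned radii alone already exceed the requested total area/perimeter."""


class OverlapError(NumstimError):
    """Hull refinement forced two elements to intersect before convergence."""


class MaxIterationError(NumstimError):
    """An iterative procedure hit its iteration cap without converging."""
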