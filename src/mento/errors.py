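"""Exception hierarchy shared across the package.

Every error raised by the public API derives from :class:`MentoError`, so
batch drivers can catch one base class and triage by subclass (the CLI maps
each subclass to a stable exit code).
"""


class MentoError(Exception):
    """Base class for all package errors."""


class ModelFormatError(MentoError):
    """A model file could not be parsed in the requested dialect."""


class ModelValidationError(MentoError):
    """A parsed model violates a structural invariant.

    Raised for a missing biomass reaction, an exchange reaction touching
    more than one metabolite, inverted bounds, or duplicate identifiers.
    """


class MassUnavailableError(MentoError):
    """A metabolite's molar mass could not be resolved.

    Neither an explicit ``molar_mass`` annotation nor a parsable chemical
    formula was available.  Generic residue formulas (``R`` groups) are
    deliberately treated as unresolvable rather than silently assigned a
    mass.
    """

    def __init__(self, metabolite_ids, message=None):
        self.metabolite_ids = list(metabolite_ids)
        super().__init__(
            message
            or "molar mass unavailable for: " + ", ".join(self.metabolite_ids)
        )


class SolverError(MentoError):
    """The LP/MILP backend failed with an unexpected status."""

    def __init__(self, status, message=""):
        self.status = status
        super().__init__(message or f"solver failed with status {status!r}")


class InfeasibleTargetError(MentoError):
    """The biomass cutoff is unattainable even with every exchange open."""


class MilpTimeoutError(MentoError):
    """A MILP solve hit its time limit.

    Carries the incumbent objective and best bound so callers can decide
    whether the incumbent is usable.
    """

    def __init__(self, incumbent=None, bound=None):
        self.incumbent = incumbent
        self.bound = bound
        super().__init__(
            f"MILP time limit reached (incumbent={incumbent}, bound={bound})"
        )


class PreconditionError(MentoError, ValueError):
    """An operation's documented precondition was violated by the caller."""


class UnknownIdentifierError(MentoError, KeyError):
    """A gene, organism, or metabolite id is not known to the object."""
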