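"""Exception hierarchy shared across the package."""


class ThermoEFMError(Exception):
    """Base class for all package errors."""


class FormatError(ThermoEFMError):
    """A file could not be parsed (malformed SBML, bad TSV, ...)."""


class ValidationError(ThermoEFMError):
    """An input violates a structural invariant (unknown ids, empty model, ...)."""


class ConflictError(ThermoEFMError):
    """Mutually contradictory direction constraints."""


class ConfigurationError(ThermoEFMError):
    """Missing thermodynamic annotation or configuration entry."""


class InfeasibleSystemError(ThermoEFMError):
    """The linear constraint system admits no solution.

    Carries the names of constraints implicated in the infeasibility when a
    relaxation analysis could identify them.
    """

    def __init__(self, message: str, implicated: tuple[str, ...] = ()):
        super().__init__(message)
        self.implicated = implicated


class ModelInconsistencyError(ThermoEFMError):
    """Both directions of a reaction are thermodynamically impossible."""


class StateError(ThermoEFMError):
    """Operation called in the wrong state (e.g. range estimation on an
    infeasible pattern)."""


class CapacityError(ThermoEFMError):
    """Enumeration exceeded the configured mode-count cap."""


class SolverStatusError(ThermoEFMError):
    """LP solver returned an unexpected status (infeasible/unbounded)."""
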