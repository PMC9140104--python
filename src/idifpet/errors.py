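"""Exception hierarchy for the IDIF pipeline."""


class IdifError(Exception):
    """Base class for all package errors."""


class SchemaError(IdifError):
    """Input files disagree with each other (e.g. frame count vs timing rows)."""


class FormatError(IdifError):
    """An input file is not in the expected format."""


class ScheduleError(IdifError):
    """A frame schedule cannot support the requested operation."""


class EmptyRegionError(IdifError):
    """A named region has no voxels in the label map."""


class DegenerateGeometryError(IdifError):
    """Image geometry leaves no usable slices (e.g. cerebellum at FOV bottom)."""


class ParameterError(IdifError):
    """A kinetic parameter set violates its constraints."""


class DegenerateFactorError(IdifError):
    """The component matrix H is rank-deficient; weights are not identifiable."""


class NonIdentifiableError(IdifError):
    """The weight matrix W is rank-deficient; scaling factors are not identifiable."""


class ConvergenceError(IdifError):
    """No optimizer start converged."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class StateError(IdifError):
    """An InputFunction is in the wrong unit state for the requested operation."""


class InsufficientDataError(IdifError):
    """Too few usable samples (e.g. < 3 frames in the Logan window)."""


class CoverageError(IdifError):
    """A time grid does not cover the requested interval."""


class ConfigError(IdifError):
    """Pipeline configuration is invalid or incomplete."""
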