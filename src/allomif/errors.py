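"""Exception hierarchy shared across the analysis stages."""


class AllomifError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AllomifError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(AllomifError, ValueError):
    """An input file could not be parsed or is internally inconsistent."""


class GeometryError(AllomifError, ValueError):
    """Degenerate geometry (collinear gate triangle, coincident atoms, ...)."""


class MissingAtomError(AllomifError, KeyError):
    """An atom or residue key was not found in a structure or topology."""


class InsufficientPairingError(AllomifError, ValueError):
    """Too few paired atoms (or residues) for the requested computation."""


class UndersamplingError(ParameterError):
    """Too few samples for a statistical estimator to be meaningful."""


class FitError(AllomifError, RuntimeError):
    """A nonlinear fit failed to converge."""


class ConfigError(AllomifError, ValueError):
    """A pipeline configuration document failed schema validation."""
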