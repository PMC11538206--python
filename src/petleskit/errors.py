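"""Exception hierarchy shared across the toolkit."""


class PetlesError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PetlesError):
    """A file is not a readable 3D volume of the expected kind."""


class ValidationError(PetlesError):
    """Array content violates a role contract (e.g. fractional mask values)."""


class MetadataError(PetlesError):
    """Required PET metadata (dose, weight) is missing or invalid."""


class GeometryError(PetlesError):
    """Volumes are misaligned or share no physical overlap."""


class ParameterError(PetlesError):
    """A user-supplied parameter is out of its valid range."""


class SpecError(PetlesError):
    """A phantom specification cannot be realized (e.g. placement failure)."""


class InsufficientDataError(PetlesError):
    """Too few valid observations to compute a statistic."""


class ReportError(PetlesError):
    """A report bundle is missing required components."""
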