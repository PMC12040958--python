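"""Exception types shared across the package."""


class EcgVaeError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometry(EcgVaeError):
    """Imaging planes are parallel/coplanar and do not define a point or frame."""


class FrameMismatch(EcgVaeError):
    """An electrode layout is already expressed in the requested frame."""


class InvalidBand(EcgVaeError):
    """Band-pass edges are inconsistent with each other or the sampling rate."""


class NoBeatsFound(EcgVaeError):
    """Fewer than two R peaks were detected in a record."""


class ShapeMismatch(EcgVaeError):
    """An array does not have the shape the model expects."""


class ConditionSchemaMismatch(EcgVaeError):
    """A condition vector does not match the schema the model was built with."""


class DataTooSmall(EcgVaeError):
    """Training dataset is smaller than the minimum the trainer supports."""


class UntrainedModel(EcgVaeError):
    """Generation was requested from a model that has not been fitted."""


class MissingElectrode(EcgVaeError):
    """A required electrode is absent from a potential map or layout."""


class SingularPoint(EcgVaeError):
    """Field point coincides with the dipole source."""


class ConfigError(EcgVaeError):
    """An experiment configuration is internally inconsistent."""


class SplitMismatch(EcgVaeError):
    """Experiment arms being compared were evaluated on different test subjects."""
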