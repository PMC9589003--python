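"""Exception and warning types shared across the package."""


class GaitTraitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GaitTraitError):
    """A keypoint file or table does not follow the expected layout."""


class DataQualityError(GaitTraitError):
    """Input data are structurally valid but unusable (e.g. too many dropouts)."""


class DegenerateGeometryError(GaitTraitError):
    """A geometric quantity is undefined (zero-length bone vector)."""


class FacingDetectionError(GaitTraitError):
    """No face-toward interval could be found in a sequence."""


class GaitWarning(UserWarning):
    """Non-fatal data-quality or configuration warnings."""
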