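"""Exception hierarchy shared across the package."""


class BaDiagError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BaDiagError, ValueError):
    """Invalid configuration value (prevalence, scale, geometry ...)."""


class InputError(BaDiagError, ValueError):
    """Invalid data passed to an operation."""


class AnnotationError(InputError):
    """ROI annotation inconsistent with its image (out-of-bounds box ...)."""


class DegenerateImageError(InputError):
    """Image cannot be normalized (zero interquartile range)."""

    def __init__(self, source_id: str):
        self.source_id = source_id
        super().__init__(
            f"image {source_id!r} has zero interquartile range; "
            "intensity normalization is undefined"
        )


class DelineationFailure(BaDiagError):
    """Morphological delineation produced an empty mask.

    Downstream code treats the affected view as missing rather than
    aborting the whole patient.
    """


class PatientExcluded(BaDiagError):
    """Patient fails an inclusion rule (e.g. no ROI visible in any view)."""

    def __init__(self, patient_id: str, reason: str):
        self.patient_id = patient_id
        self.reason = reason
        super().__init__(f"patient {patient_id!r} excluded: {reason}")


class SchemaError(InputError):
    """Feature names or table columns do not match the expected schema."""
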