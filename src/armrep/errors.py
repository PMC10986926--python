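"""Exception hierarchy shared across the package."""


class ArmRepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ArmRepError):
    """A file does not conform to the expected layout (missing/renamed columns)."""


class DataError(ArmRepError):
    """File parsed but the data violate an invariant (non-monotonic time, overlap...)."""


class VocabularyError(DataError):
    """A categorical value is outside its closed vocabulary."""


class ParameterError(ArmRepError):
    """An analysis parameter is out of its valid range."""


class CalibrationError(ArmRepError):
    """The calibration window does not satisfy the quasi-static requirements."""


class SpecError(ArmRepError):
    """A synthetic session specification is internally inconsistent."""
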