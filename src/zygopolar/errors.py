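"""Exception hierarchy for the zygopolar pipeline.

Every error raised by the package derives from :class:`ZygopolarError`, so
callers can catch pipeline failures without masking programming errors.
"""


class ZygopolarError(Exception):
    """Base class for all zygopolar errors."""


class AxisInferenceError(ZygopolarError):
    """Stack axis layout could not be inferred and no hint was supplied."""


class EmptyMaskError(ZygopolarError):
    """A cell mask contains no foreground pixels."""


class DegenerateAxisError(ZygopolarError):
    """The mask is too isotropic (or collinear) to define a major axis."""


class DisconnectedMaskError(ZygopolarError):
    """An interior axial row of the oriented mask contains no cell pixels."""


class FlatProfileError(ZygopolarError):
    """A profile has zero variance and cannot be z-scored."""


class ManifestError(ZygopolarError):
    """Dataset manifest failed validation.

    Carries the full list of violations, not just the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "manifest validation failed:\n" + "\n".join(
            f"  - {v}" for v in self.violations
        )
        super().__init__(msg)
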