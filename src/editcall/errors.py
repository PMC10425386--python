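"""Exception types shared across the pipeline."""


class EditcallError(Exception):
    """Base class for all package-specific errors."""


class GuideNotFoundError(EditcallError):
    """The protospacer+PAM was not found in the reference amplicon."""


class AmbiguousGuideError(EditcallError):
    """The protospacer+PAM occurs more than once in the reference amplicon."""


class PamError(EditcallError):
    """The PAM does not match the SpCas9 NGG requirement."""


class ArmMismatchError(EditcallError):
    """Donor homology arms were not found flanking the cut site."""


class InconsistentSpecError(EditcallError):
    """A simulation or run request contradicts the experiment design."""


class LowQualityError(EditcallError):
    """Read failed the mean base-quality filter."""


class EmptyInputError(EditcallError):
    """No mapped reads to aggregate."""


class ConstructionFailureError(EditcallError):
    """The fixture generator could not satisfy its constraints."""
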