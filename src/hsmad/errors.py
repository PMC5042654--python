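"""Exception types shared across the package."""


class HsmadError(Exception):
    """Base class for all package-specific errors."""


class InvalidGridError(HsmadError, ValueError):
    """A wavelength axis is non-uniform, non-monotone, or mismatched."""


class DegenerateSpectrumError(HsmadError, ValueError):
    """A spectrum is all-zero or non-finite where positive data is required."""


class UnsupportedFormatError(HsmadError, ValueError):
    """An ENVI header declares an interleave or data type we do not read."""


class InvalidReferenceError(HsmadError, ValueError):
    """A lamp reference spectrum is non-positive somewhere."""


class SegmentationError(HsmadError, RuntimeError):
    """Adaptive histogram thresholding failed to find a background minimum."""

    def __init__(self, message, histogram=None):
        super().__init__(message)
        #: the resampled (intensity, count) histogram, for diagnostics
        self.histogram = histogram


class EmptyTrainingError(HsmadError, ValueError):
    """No candidate pixels were available to train on."""


class NPClusterSelectionError(HsmadError, ValueError):
    """The nanoparticle cluster could not be selected automatically."""


class UndefinedQuantityError(HsmadError, ZeroDivisionError):
    """A ratio's denominator (tissue pixels, ROI pixels) is empty."""
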