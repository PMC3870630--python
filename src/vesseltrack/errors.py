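"""Exception hierarchy for the tracking pipeline."""


class VesselTrackError(Exception):
    """Base class for all package errors."""


class ImageFormatError(VesselTrackError):
    """Unreadable file or unsupported raster layout / bit depth."""


class DegenerateFOVError(VesselTrackError):
    """Field-of-view threshold left no pixels."""


class UndefinedDirectionError(VesselTrackError):
    """All gradient magnitudes vanish in the analysis window."""


class WindowDegenerateError(VesselTrackError):
    """Too few in-image candidate points survive on a search window."""


class InvalidConfigurationError(VesselTrackError):
    """A configuration hypothesis is geometrically meaningless."""


class NoConfigurationError(VesselTrackError):
    """No feasible configuration remains after pruning."""


class StatisticsUnavailableError(VesselTrackError):
    """The moving statistics regions fall entirely outside the image."""


class SpecError(VesselTrackError):
    """Invalid phantom or run specification."""
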