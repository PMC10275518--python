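"""Exception hierarchy.

Every stage raises a subclass of :class:`BBBQError` so pipeline callers can
catch one type and still report which contract was violated.
"""


class BBBQError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BBBQError):
    """Invalid generator or run configuration."""


class InputFormatError(BBBQError):
    """Unreadable or unsupported input file."""


class ROIFormatError(BBBQError):
    """Malformed region-of-interest polygon file."""


class DegenerateROIError(BBBQError):
    """ROI construction produced an empty or one-sided region."""


class DegenerateSummaryError(BBBQError):
    """All pixels of a region were excluded from the hue summary."""


class UndefinedRatioError(BBBQError):
    """Contralateral mean is non-positive; the stain ratio is undefined."""


class FormulaError(BBBQError):
    """Elemental formula does not parse or uses an unknown element."""


class UnsupportedElementError(FormulaError):
    """Element missing from the monoisotopic mass table."""


class SpecificationError(BBBQError):
    """A molecule/adduct specification lacks required mass information."""


class MSIFormatError(BBBQError):
    """Invalid imzML content or an empty dataset."""


class ExtractionError(BBBQError):
    """Ion-image extraction target outside the acquired m/z range."""
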