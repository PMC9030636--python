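"""Exception and warning types shared across the package.

Exit-code mapping used by the CLI: input/format problems exit 2, degenerate
geometry exits 3, statistics errors exit 4.
"""


class ScalaFitError(Exception):
    """Base class for all package errors."""


class ParameterError(ScalaFitError, ValueError):
    """A numeric argument is non-finite or outside its documented range."""


class InputFormatError(ScalaFitError, ValueError):
    """A file or table does not conform to the documented dialect."""


class CoverageError(ScalaFitError, ValueError):
    """A template does not cover the angular range a query requires."""


class DegenerateGeometryError(ScalaFitError, ValueError):
    """Coincident or collinear points where a non-degenerate frame is needed."""


class EmptyCropError(ScalaFitError, ValueError):
    """An angular crop removed every face of the mesh."""


class BankError(ScalaFitError, ValueError):
    """Template-bank construction or lookup failed."""


class TranslocationSpecError(ScalaFitError, ValueError):
    """A translocation scenario is inconsistent with the array geometry."""


class StatisticsError(ScalaFitError, ValueError):
    """An agreement statistic is undefined for the given table."""


class UndefinedKappaError(StatisticsError):
    """Chance agreement equals 1 (all ratings in one category): kappa undefined."""


class ChiralityWarning(UserWarning):
    """A reflection fits the landmark correspondence far better than a rotation.

    Emitted when the source landmarks appear to come from the contralateral
    (mirror-image) side; the caller should use a side-matched template instead.
    """


class EdgeExtrapolationWarning(UserWarning):
    """A query point projects onto the template boundary; the local tangent
    plane was extended beyond the segmented ribbon."""
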