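"""Exception hierarchy for plgfbind.

All errors raised by the package derive from :class:`PlgfBindError` so callers
can catch everything with one handler; concrete subclasses also inherit from
the matching builtin (``ValueError``) so untargeted code behaves sensibly.
"""


class PlgfBindError(Exception):
    """Base class for all plgfbind errors."""


class DomainError(PlgfBindError, ValueError):
    """An input is outside the physically meaningful domain (e.g. negative concentration)."""


class InvalidAnalyteError(PlgfBindError, ValueError):
    """Analyte specification is unusable (non-positive molecular weight, unknown name)."""


class UndefinedOccupancyError(PlgfBindError, ValueError):
    """Occupancy is 0/0: both the dissociation constant and the free ligand are zero."""


class NotEstimableError(PlgfBindError, ValueError):
    """K_D cannot be estimated from this sample (total PlGF not above free PlGF)."""


class InconsistentSampleError(PlgfBindError, ValueError):
    """Implied bound ligand meets or exceeds total receptor; sample violates the model."""


class NoEstimableSamplesError(PlgfBindError, ValueError):
    """No sample in the collection admits a K_D estimate."""


class InputError(PlgfBindError, ValueError):
    """Malformed statistical input (wrong lengths, too few observations, empty data)."""


class NotFittableError(PlgfBindError, ValueError):
    """Regression input is degenerate (zero variance in the predictor)."""


class UndefinedRatioError(PlgfBindError, ValueError):
    """sFlt-1/PlGF ratio is undefined because free PlGF is zero."""


class IncompleteRecordError(PlgfBindError, ValueError):
    """A clinical record lacks fields required by a classification rule."""


class ConfigError(PlgfBindError, ValueError):
    """Simulator configuration is inconsistent with the requested mode."""


class SchemaError(PlgfBindError, ValueError):
    """A sample table is missing required columns or has unparsable values."""
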