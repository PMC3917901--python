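"""Exception hierarchy for the unmixing pipeline."""


class PlatemixError(Exception):
    """Base class for all package errors."""


class SchemaError(PlatemixError):
    """A CSV file does not conform to the canonical column schema."""


class LayoutError(PlatemixError):
    """Plate layout is inconsistent with the measured wells."""


class DataError(PlatemixError):
    """Well time series violate structural invariants (ordering, completeness)."""


class FitError(PlatemixError):
    """Hyperparameter optimization failed on every attempted path.

    Carries the best-so-far state (if any) in ``best_state``.
    """

    def __init__(self, message, best_state=None):
        super().__init__(message)
        self.best_state = best_state


class NumericalError(PlatemixError):
    """Covariance factorization failed even after jitter escalation."""


class CalibrationError(PlatemixError):
    """OD calibration could not produce a monotone density map."""


class EstimationError(PlatemixError):
    """An estimator was left with no usable data points."""


class SamplerError(PlatemixError):
    """Rejection sampler envelope mis-specified (acceptance rate collapsed)."""
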