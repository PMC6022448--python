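"""Exception hierarchy for treatbenefit.

All package-specific failures derive from :class:`TreatBenefitError` so
callers (and the CLI) can distinguish module errors from programming bugs.
"""


class TreatBenefitError(Exception):
    """Base class for all treatbenefit errors."""


class SchemaError(TreatBenefitError):
    """Input table or marker schema does not match the declared contract."""


class DataValueError(TreatBenefitError, ValueError):
    """A cell value violates the declared marker levels or 0/1 coding."""


class SpecError(TreatBenefitError, ValueError):
    """A synthetic-trial specification is internally inconsistent."""


class DesignError(TreatBenefitError):
    """The model design matrix is rank deficient."""


class DegenerateDesignError(TreatBenefitError):
    """A trial arm is empty, so no treatment contrast is estimable."""


class FitError(TreatBenefitError):
    """Maximum-likelihood fitting failed (non-convergence or separation)."""


class ShrinkageError(FitError):
    """Too many bootstrap resamples failed during shrinkage estimation."""


class UndefinedEstimateError(TreatBenefitError):
    """A subgroup event-rate contrast is undefined (an arm is empty)."""


class CIError(TreatBenefitError):
    """Bootstrap confidence-interval construction failed."""
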