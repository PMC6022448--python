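import numpy as np
import pandas as pd
import pytest

from treatbenefit import (
    MarkerSpec,
    TreatmentBenefitResults,
    TrialDataset,
    example_pessary_trial_spec,
)

# Saturated single-binary-marker micro trial: event counts per
# (arm, marker) cell chosen so the saturated logistic fit has a
# contingency-table closed form.
MICRO_CELLS = [  # (treatment, x, events, total)
    (0, "0", 10, 100),
    (0, "1", 30, 100),
    (1, "0", 20, 100),
    (1, "1", 15, 100),
]

MICRO_TRUTH = {
    "intercept": np.log(10 / 90),
    "x": np.log((30 / 70) / (10 / 90)),
    "treatment": np.log((20 / 80) / (10 / 90)),
    "treatment:x": np.log((15 / 85) / (20 / 80)) - np.log((30 / 70) / (10 / 90)),
}


def build_micro_trial() -> TrialDataset:
    treatment, outcome, marker = [], [], []
    for t, x, events, total in MICRO_CELLS:
        treatment += [t] * total
        outcome += [1] * events + [0] * (total - events)
        marker += [x] * total
    specs = (MarkerSpec("x", "binary", ("0", "1"), "0"),)
    return TrialDataset(np.array(treatment), np.array(outcome),
                        pd.DataFrame({"x": marker}), specs)


@pytest.fixture(scope="session")
def micro_trial() -> TrialDataset:
    return build_micro_trial()


@pytest.fixture(scope="session")
def pessary_spec():
    return example_pessary_trial_spec()


def build_reference_model(bse: float = 0.5) -> TreatmentBenefitResults:
    """The worked-example pessary model with its shrunken coefficients.

    Standard errors are synthetic placeholders; only the point
    coefficients are meaningful.
    """
    spec = example_pessary_trial_spec()
    params = spec.coefficient_vector
    return TreatmentBenefitResults(
        coefficient_names=list(params.index),
        params=params,
        bse=pd.Series(bse, index=params.index),
        shrinkage_factor=0.76,
        is_shrunken=True,
        marker_specs=spec.marker_specs,
        threshold=0.0)


@pytest.fixture(scope="session")
def reference_model() -> TreatmentBenefitResults:
    return build_reference_model()
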