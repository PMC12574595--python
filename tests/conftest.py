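import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poppk import (
    DoseRegimen,
    ModelKind,
    PKParameters,
    SubjectRecord,
    predict_conc,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_subject(
    params: PKParameters,
    kind: ModelKind,
    dose: float = 100.0,
    times=None,
    noise_sd: float = 0.0,
    rng=None,
    subject_id: str = "S1",
    covariates=None,
) -> SubjectRecord:
    """Noise-free (or proportionally noisy) subject from known parameters."""
    kind = ModelKind(kind)
    if times is None:
        times = np.linspace(0.0 if not kind.has_absorption else 0.25, 24.0, 10)
    regimen = DoseRegimen(dose, kind.route)
    conc = predict_conc(params, regimen, np.asarray(times, float), kind)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        conc = np.clip(conc * (1 + rng.normal(0, noise_sd, conc.shape)), 0, None)
    return SubjectRecord(
        subject_id=subject_id,
        dose=regimen,
        times=np.asarray(times, float),
        concentrations=conc,
        covariates=covariates or {},
    )


@pytest.fixture(scope="session")
def onecomp_truth():
    return PKParameters(cl=5.0, v=50.0)


@pytest.fixture(scope="session")
def twocomp_truth():
    return PKParameters(cl=5.0, v=30.0, v2=50.0, q=10.0)
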