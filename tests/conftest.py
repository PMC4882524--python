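import warnings

import pytest

import traitsem as ts

# two-indicator latents are deliberate throughout the study models
warnings.filterwarnings(
    "ignore", message="latent .* has exactly 2 indicators"
)


@pytest.fixture(scope="session")
def study_moments() -> ts.CorrMatrix:
    return ts.study_correlations()


@pytest.fixture(scope="session")
def models() -> dict[str, ts.ModelSpec]:
    return ts.model_library()


@pytest.fixture(scope="session")
def nmass_fit(models, study_moments) -> ts.FitResult:
    return ts.fit_ml(models["nmass_final"], study_moments, seed=1)


@pytest.fixture(scope="session")
def narea_fit(models, study_moments) -> ts.FitResult:
    return ts.fit_ml(models["narea_final"], study_moments, seed=1)
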