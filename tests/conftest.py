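import numpy as np
import pytest

from phenoscreen.simulate import (
    FeatureSimSpec,
    ImageSimSpec,
    render_synthetic_field,
    simulate_control_population,
)
from phenoscreen.scoring import fit_control_model


@pytest.fixture(scope="session")
def feature_spec() -> FeatureSimSpec:
    return FeatureSimSpec.default()


@pytest.fixture(scope="session")
def control_model(feature_spec):
    """Robust control model fitted on a clean simulated population."""
    controls = simulate_control_population(feature_spec, 3000, seed=11)
    return fit_control_model(controls)


@pytest.fixture(scope="session")
def rendered_field():
    """A low-noise synthetic field with its ground truth."""
    spec = ImageSimSpec(n_cells=15, noise_sd=10.0)  # ~1% of body signal
    channels, truth = render_synthetic_field(spec, seed=5)
    return spec, channels, truth


def random_correlated_instance(rng: np.random.Generator, n: int, p: int):
    """A full-rank correlated normal sample with its true parameters."""
    A = rng.normal(size=(p, p))
    cov = A @ A.T + np.eye(p)
    mean = rng.normal(scale=3.0, size=p)
    X = mean + rng.standard_normal((n, p)) @ np.linalg.cholesky(cov).T
    return X, mean, cov
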