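import numpy as np
import pytest

from lqhet import (
    GaussianHeterogeneityParams,
    GridConfig,
    build_grid,
    fixture_tumors,
)

# Published-caption parameter sets used across the suite.
OE33 = GaussianHeterogeneityParams(0.40, 0.020, 6.5e-2, 3.5e-3)
PROSTATE = {
    0.43: GaussianHeterogeneityParams(0.43, 0.020, 1.0e-1, 3.5e-3),
    0.35: GaussianHeterogeneityParams(0.35, 0.020, 1.0e-1, 3.5e-3),
    0.30: GaussianHeterogeneityParams(0.30, 0.020, 1.0e-1, 3.5e-3),
}


@pytest.fixture(scope="session")
def oe33_params():
    return OE33


@pytest.fixture(scope="session")
def oe33_grid():
    return build_grid(OE33, GridConfig())


@pytest.fixture(scope="session")
def tumors():
    return fixture_tumors()


def truncated_gaussian_sample(params, cutoff, n, rng):
    """Independent Monte-Carlo oracle: rejection-sample the truncated Gaussian.

    Draws from the untruncated axis-aligned Gaussian and keeps points whose
    standardized squared radius is <= 2 ln(1/cutoff), i.e. where the
    unnormalized weight is >= cutoff.
    """
    za = rng.standard_normal(n)
    zb = rng.standard_normal(n)
    keep = za**2 + zb**2 <= 2.0 * np.log(1.0 / cutoff)
    return params.alpha_c + params.sigma_alpha * za[keep], params.beta_c + params.sigma_beta * zb[keep]
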