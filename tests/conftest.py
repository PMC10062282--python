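import dataclasses

import numpy as np
import pytest

import expectmon as em


@dataclasses.dataclass
class FittedData:
    model: object
    x: np.ndarray
    y: np.ndarray
    fit: em.ExpectileFit


@pytest.fixture(scope="session")
def gompertz_data():
    """A fixed Gompertz fit on synthetic historical data (tau = 1/2)."""
    rng = np.random.default_rng(7)
    model = em.gompertz2_model()
    x = rng.uniform(0.0, 1.0, 120)
    y = model.predict(x.reshape(-1, 1), [10.0, 5.0]) + rng.standard_normal(120)
    return FittedData(model, x, y, em.fit_expectile(model, x, y, 0.5))


@pytest.fixture(scope="session")
def gompertz_fit(gompertz_data):
    return gompertz_data.fit
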