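import numpy as np
import pytest

import glomnet as gn


@pytest.fixture(scope="session")
def protocol_dataset():
    """One subject, one odor, full 30-trial protocol with a planted network."""
    cfg = gn.SimulationConfig(n_subjects=1, n_odors=1, n_trials=30,
                              n_glomeruli=10, missing_prob=0.0, seed=11)
    net = gn.make_network(10, 0.12, cfg.coupling_strength, seed=12)
    raw, truth = gn.simulate_dataset(cfg, net)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def protocol_tensor(protocol_dataset):
    _, raw, _ = protocol_dataset
    return gn.dff_normalize(raw)


def simulate_var(coeffs: np.ndarray, n: int, rng: np.random.Generator,
                 noise_sd=1.0, burn: int = 200) -> np.ndarray:
    """Plain VAR simulator used as an independent data source in tests."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p, M, _ = coeffs.shape
    noise_sd = np.broadcast_to(noise_sd, (M,))
    x = np.zeros((n + burn, M))
    e = rng.normal(0.0, 1.0, size=(n + burn, M)) * noise_sd
    for t in range(n + burn):
        acc = e[t].copy()
        for k in range(min(p, t)):
            acc += coeffs[k] @ x[t - 1 - k]
        x[t] = acc
    return x[burn:]
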