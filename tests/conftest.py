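import numpy as np
import pytest

from dnamech.datasets import jfactor_rows, load_mechanical_presets, preset_params
from dnamech.wlc_fit import JFactorDataset, fit_wlc


@pytest.fixture(scope="session")
def presets():
    return load_mechanical_presets()


@pytest.fixture(scope="session")
def dna1_params():
    return preset_params("DNA1")


@pytest.fixture(scope="session")
def dna1_dataset():
    return JFactorDataset.from_dataframe(jfactor_rows("DNA1"))


@pytest.fixture(scope="session")
def dna1_fit(dna1_dataset):
    return fit_wlc(dna1_dataset, seed=1)


@pytest.fixture(scope="session")
def all_fits():
    """WLC fits to all nine published J-factor datasets."""
    out = {}
    for i in range(1, 10):
        label = f"DNA{i}"
        ds = JFactorDataset.from_dataframe(jfactor_rows(label))
        out[label] = fit_wlc(ds, seed=1)
    return out


def make_synthetic_dataset(params, lengths, noise, seed, label="synthetic"):
    """Noisy J-factor dataset straight from the model (test helper)."""
    from dnamech.wlc_model import jfactor_model

    rng = np.random.default_rng(seed)
    n_bp = np.asarray(lengths, dtype=float)
    j = np.asarray(jfactor_model(n_bp, params))
    if noise > 0:
        eps = rng.normal(0, noise, size=j.shape)
        eps = np.clip(eps, -0.9, None)
        mean = j * (1 + eps)
        sd = noise * mean
    else:
        mean = j.copy()
        sd = np.full_like(j, max(1e-8, 1e-2 * j.min()))
    return JFactorDataset(label, n_bp, mean, sd)
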