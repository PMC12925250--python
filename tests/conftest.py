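import numpy as np
import pytest

import spaco


@pytest.fixture(scope="session")
def lattice6():
    return spaco.make_lattice(6, 6)


@pytest.fixture(scope="session")
def grid6(lattice6):
    return spaco.build_grid_weights(lattice6)


@pytest.fixture(scope="session")
def torus12():
    return spaco.make_lattice(12, 12, torus=True)


@pytest.fixture(scope="session")
def torus_weights(torus12):
    return spaco.build_grid_weights(torus12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def fitted_small():
    """A selected model on a 12x12 lattice with clear spatial signal."""
    X, coords, truth = spaco.simulate_dataset(
        spaco.SyntheticSpec(n_spatial_genes=20, n_noise_genes=30, seed=5)
    )
    Xn = spaco.log_normalize(X)
    model, L, Xw = spaco.fit_pipeline(Xn, coords, seed=17, permutations=300)
    assert model.k and model.k >= 1
    return {
        "model": model,
        "L": L,
        "Xw": Xw,
        "coords": coords,
        "scaled": spaco.z_transform(Xn),
        "truth": truth,
        "counts": X,
    }
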