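import numpy as np
import pytest

import cytoblast as cb


@pytest.fixture(scope="session")
def panel():
    return cb.default_panel()


@pytest.fixture(scope="session")
def trajectory():
    return cb.default_trajectory()


@pytest.fixture(scope="session")
def healthy_scaled(panel, trajectory):
    """A preprocessed healthy pool shared across tests: (arcsinh, scaled, scaler, stages)."""
    m, stages = cb.simulate_healthy(6000, trajectory, seed=101)
    arc = cb.arcsinh_transform(m, panel)
    scaler = cb.fit_minmax(arc)
    return arc, cb.apply_minmax(scaler, arc), scaler, stages


@pytest.fixture(scope="session")
def trained_ae(healthy_scaled):
    """A small trained autoencoder shared across tests."""
    _, scaled, scaler, _ = healthy_scaled
    cfg = cb.AEConfig(layer_widths=(23, 16, 8), latent_dim=4, epochs=20, seed=3)
    return cb.train_autoencoder(scaled, cfg, scaler=scaler)


def random_cell_matrix(n_cells, channels, seed=0, state="arcsinh"):
    rng = np.random.default_rng(seed)
    return cb.CellMatrix(
        values=rng.normal(2.0, 1.0, size=(n_cells, len(channels))),
        channels=list(channels),
        state=state,
    )
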