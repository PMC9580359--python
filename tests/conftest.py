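import numpy as np
import pytest

import tfbcsp as t

# all test seeds fixed a priori
SEED = 1234


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def small_config():
    """Tiny 2-band x 2-window grid for fast pipeline mechanics tests."""
    return t.RunConfig(
        band_lo=6.0, band_hi=18.0, band_width=6.0, band_step=6.0,
        window_lo=500.0, window_hi=2500.0, window_length=1000.0, window_step=1000.0,
        broadband=(4.0, 30.0), m=1, folds=5, inner_folds=5, seed=SEED,
    )


@pytest.fixture(scope="session")
def small_planted(small_config):
    """20 trials/class, 4 channels, effect planted in band [12,18] x window
    [1500,2500] = cell index 3 of the small grid."""
    pattern = tuple(np.random.default_rng(SEED).standard_normal(4))
    spec = t.SynthSpec(
        n_trials_per_class=20, n_channels=4, fs=250.0, epoch_ms=3000.0,
        planted_cells=[t.PlantedCell(t.BandSpec(12.0, 18.0),
                                     t.WindowSpec(1500.0, 2500.0),
                                     2.5, pattern)],
        seed=SEED,
    )
    epochs, truth = t.generate(spec)
    return epochs, truth


@pytest.fixture(scope="session")
def random_epochs():
    """Unstructured two-class noise epochs for contract-level tests."""
    g = np.random.default_rng(SEED + 1)
    data = g.standard_normal((24, 5, 300))
    labels = np.array(["left"] * 12 + ["right"] * 12)
    return t.EpochSet(data, labels, fs=100.0, t0=0.0)
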