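import numpy as np
import pytest

from ecgireg import DatasetConfig, decompose, generate_dataset, make_transfer_matrix


SMALL_CONFIG = dict(
    n_heart=60, n_torso=24, n_recording=12, n_beats=3,
    duration=400.0, seed=7,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset shared by the slower integration tests."""
    return generate_dataset(DatasetConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_tm(small_dataset):
    return decompose(small_dataset.A)


def noisy_instance(seed, n_body=10, n_heart=14, snr_db=20.0, decay=0.35):
    """Random ill-conditioned instance with body potentials at a given SNR.

    Returns ``(tm, b)``: a decomposed spectral-mode transfer matrix and a
    noisy body-potential vector generated from a random source.
    """
    rng = np.random.default_rng(seed)
    A = make_transfer_matrix(
        mode="spectral", n_body=n_body, n_heart=n_heart,
        spectral_decay=decay, seed=seed,
    )
    h = rng.standard_normal(n_heart)
    b_clean = A @ h
    noise = rng.standard_normal(n_body)
    b = b_clean + noise * np.sqrt(np.mean(b_clean**2) / 10 ** (snr_db / 10))
    return decompose(A), b
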