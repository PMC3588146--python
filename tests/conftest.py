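import numpy as np
import pytest

from sigdecipher import build_alphabet
from sigdecipher.nmf import ExposureMatrix, SignatureMatrix


@pytest.fixture(scope="session")
def sbs6():
    return build_alphabet("SBS6")


@pytest.fixture(scope="session")
def sbs96():
    return build_alphabet("SBS96")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def make_signatures(K, N, rng, alphabet=None, concentration=0.5):
    """Random column-stochastic K×N signature matrix."""
    P = rng.dirichlet(np.full(K, concentration), size=N).T
    return SignatureMatrix(P=P, names=[f"S{i+1}" for i in range(N)], alphabet=alphabet)


def make_exposures(N, G, rng, scale=1000):
    E = rng.integers(1, scale, size=(N, G)).astype(float)
    return ExposureMatrix(
        E=E, names=[f"S{i+1}" for i in range(N)], samples=[f"G{i+1}" for i in range(G)]
    )
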