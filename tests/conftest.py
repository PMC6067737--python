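"""Shared fixtures: backends, synthetic corpora, a small trained model."""

from __future__ import annotations

import warnings
import zlib

import numpy as np
import pytest

from wholemir.dataset import encode_examples, generate_synthetic_dataset
from wholemir.network import NetworkSpec, build_model, train_classifier
from wholemir.thermo import ToyBackend


class StructuredStubBackend(ToyBackend):
    """Toy duplex energies plus deterministic pseudo-random accessibility.

    The plain toy backend has no intramolecular structure, so every
    dG_open is 0; this stub derives a stable pseudo-random ensemble energy
    from the sequence/constraint so accessibility-threshold behaviour can
    be exercised deterministically without a folding engine.
    """

    name = "stub"

    def ensemble_energy(self, seq, unpaired=None):
        u = zlib.crc32(seq.encode()) / 0xFFFFFFFF
        e_free = -20.0 * u
        if unpaired is None:
            return e_free
        v = zlib.crc32(f"{seq}|{unpaired[0]}-{unpaired[1]}".encode()) / 0xFFFFFFFF
        return e_free * v  # >= e_free, so dG_open = e_free - e_open <= 0


@pytest.fixture(scope="session")
def toy_backend():
    return ToyBackend()


@pytest.fixture(scope="session")
def stub_backend():
    return StructuredStubBackend()


@pytest.fixture(scope="session")
def small_corpus():
    """400 planted-site examples with their miRNAs/UTRs/pairs."""
    return generate_synthetic_dataset(400, seed=123)


@pytest.fixture(scope="session")
def trained_model(small_corpus):
    """A quickly trained classifier (structure-level tests only)."""
    mirnas, _, _, examples = small_corpus
    X, y = encode_examples(examples, mirnas)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(X))
    tr, va = idx[:300], idx[300:]
    spec = NetworkSpec(seed=9, max_epochs=12, batch_size=64)
    model = build_model(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_classifier(model, X[tr], y[tr], X[va], y[va], spec)
    return model
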