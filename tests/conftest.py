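import numpy as np
import pytest

from specweight import Spectrum


@pytest.fixture
def make_spectrum():
    """Factory for small literal spectra in tests."""

    def _make(mz, intensities, precursor=500.0, identifier="s", inchikey=None):
        return Spectrum(
            precursor_mz=precursor,
            mz=np.asarray(mz, dtype=float),
            intensities=np.asarray(intensities, dtype=float),
            identifier=identifier,
            inchikey=inchikey,
        )

    return _make


@pytest.fixture
def random_spectrum_pair():
    """Factory for random spectrum pairs with continuous m/z (tie-free)."""

    def _make(rng, n_min=3, n_max=12, shared=0.5, precursor_jitter=50.0):
        n_a = int(rng.integers(n_min, n_max + 1))
        n_b = int(rng.integers(n_min, n_max + 1))
        pool = rng.uniform(60.0, 480.0, size=n_a + n_b)
        mz_a = np.sort(pool[:n_a])
        n_shared = int(shared * min(n_a, n_b))
        mz_b = np.concatenate([
            rng.choice(mz_a, size=n_shared, replace=False) + rng.normal(0, 0.01, n_shared),
            pool[n_a:n_a + n_b - n_shared],
        ])
        s_a = Spectrum(500.0, mz_a, rng.lognormal(0, 1, n_a), identifier="a")
        s_b = Spectrum(500.0 + float(rng.uniform(-precursor_jitter, precursor_jitter)),
                       np.sort(mz_b), rng.lognormal(0, 1, n_b), identifier="b")
        return s_a, s_b

    return _make
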