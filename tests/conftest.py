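import numpy as np
import pytest

from metannot import (
    FixtureSpec,
    FragmentPeak,
    LibraryRecord,
    MsmsSpectrum,
    make_synthetic_library,
)


@pytest.fixture
def two_peak_lib():
    """Library-side spectrum of the two-peak weighted-cosine fixture."""
    return MsmsSpectrum(
        spectrum_id="lib",
        precursor_mz=385.1118,
        rt=76.2,
        polarity="negative",
        peaks=(FragmentPeak(100.0, 1.0), FragmentPeak(200.0, 0.5)),
    )


@pytest.fixture
def two_peak_exp():
    """Experimental-side spectrum: same peaks shifted by ~5-10 ppm."""
    return MsmsSpectrum(
        spectrum_id="exp",
        precursor_mz=385.1118,
        rt=77.0,
        polarity="negative",
        peaks=(FragmentPeak(100.0005, 0.8), FragmentPeak(200.001, 0.6)),
    )


@pytest.fixture
def small_library():
    return make_synthetic_library(FixtureSpec(seed=11, n_compounds=12))


def weighted_cosine_oracle(mz_a, int_a, mz_b, int_b):
    """Plain-numpy cosine of the m/z-weighted vectors, assuming the i-th
    peaks of the two spectra correspond.  Independent of the package."""
    wa = np.asarray(mz_a) * np.asarray(int_a)
    wb = np.asarray(mz_b) * np.asarray(int_b)
    return float(wa @ wb / (np.linalg.norm(wa) * np.linalg.norm(wb)))
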