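import numpy as np
import pytest

from greyrank import EpochSeries, GreyPanel


def make_series(label, values, start_epoch=2010):
    values = np.asarray(values, dtype=float)
    return EpochSeries(label, tuple(range(start_epoch, start_epoch + values.size)), values)


def random_panel(rng, n_epochs=None, n_comparatives=3):
    """A positive random panel with smooth-ish series, for property tests."""
    n = n_epochs or int(rng.integers(2, 51))
    t = np.arange(n)

    def series(label):
        base = rng.uniform(0.5, 5.0)
        slope = rng.normal(0, 0.2)
        noise = rng.normal(0, 0.1, size=n)
        return make_series(label, np.maximum(base + slope * t + noise, 1e-6))

    ref = series("ref")
    comps = tuple(series(f"c{k}") for k in range(n_comparatives))
    return GreyPanel(reference=ref, comparatives=comps)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_panel():
    return GreyPanel(
        reference=make_series("burden", [2.0, 2.2, 2.5, 2.4, 2.8]),
        comparatives=(
            make_series("fruit", [1.1, 1.3, 1.5, 1.4, 1.9]),
            make_series("veg", [0.9, 1.0, 1.6, 1.2, 1.1]),
            make_series("sodium", [3.0, 2.9, 2.7, 2.9, 2.5]),
        ),
    )
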