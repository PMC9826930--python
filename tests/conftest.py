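import numpy as np
import pytest

import wormcast as wc


SIDE = 24
MAX_DAYS = 32


def small_param_law(rng: np.random.Generator) -> wc.SimulatorParams:
    """Short-lifespan plates so the tests stay fast."""
    return wc.SimulatorParams(
        n_worms=int(rng.integers(10, 16)),
        a=float(rng.uniform(5.0, 10.0)),
        b=float(rng.uniform(12.0, 20.0)),
        max_days=MAX_DAYS - 1,
        seed=int(rng.integers(2**31)),
    )


@pytest.fixture(scope="session")
def image_spec():
    return wc.ImageSpec(side=SIDE)


@pytest.fixture(scope="session")
def small_dataset(image_spec):
    return wc.build_dataset(
        12, small_param_law, seed=7, image_spec=image_spec, max_days=MAX_DAYS
    )


@pytest.fixture(scope="session")
def plate_curve():
    params = wc.SimulatorParams(n_worms=12, a=6.0, b=15.0, max_days=MAX_DAYS - 1, seed=11)
    return wc.generate_curve(params)


class StubPredictor:
    """Predictor test double: a fixed function of the count prefix."""

    def __init__(self, fn, max_days=MAX_DAYS, image_spec=wc.ImageSpec(side=SIDE)):
        from wormcast.model import ModelConfig

        self.config = ModelConfig(mode="counts_only", image_spec=image_spec,
                                  max_days=max_days)
        self._fn = fn

    def predict(self, samples):
        return np.stack([np.asarray(self._fn(s.count_prefix), dtype=float)
                         for s in samples])


@pytest.fixture
def constant_predictor():
    """Ignores its input entirely: zero output everywhere."""
    return StubPredictor(lambda prefix: np.zeros(MAX_DAYS))


@pytest.fixture
def oracle_factory():
    """Builds a stub that returns a given true curve as its prediction."""

    def make(true_curve: np.ndarray):
        padded = np.zeros(MAX_DAYS)
        padded[: len(true_curve)] = true_curve

        return StubPredictor(lambda prefix: padded.copy())

    return make
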