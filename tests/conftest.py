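import numpy as np
import pytest
from hypothesis import settings

from synscreen import ScreenSimConfig

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def reference_screen_config():
    """The documented reference screen: 303 compounds, 10 planted hits,
    inducers each killing 30% alone, Bliss excess 0.35, triplicates,
    signal noise 0.02."""

    def make(seed: int = 1, **overrides) -> ScreenSimConfig:
        kwargs = dict(
            n_compounds=303,
            hit_indices=frozenset(range(10)),
            fa_inducer={"E": 0.3, "R": 0.3},
            bliss_excess_hits=0.35,
            noise_sd=0.02,
            n_replicates=3,
            seed=seed,
        )
        kwargs.update(overrides)
        if "hit_indices" not in overrides:
            kwargs["hit_indices"] = frozenset(
                range(min(10, kwargs["n_compounds"]))
            )
        return ScreenSimConfig(**kwargs)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
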