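import numpy as np
import pytest

from idiodyn.core_io import LongitudinalSeries
from idiodyn.synthetic import RegimeSpec, generate_regime_switching, make_profiles


def planted_markov(K, T, seed, V=6, noise_sd=10.0, separation=3.0,
                   stay_prob=0.8):
    """Regime-switching scenario with symmetric stay probability."""
    profiles = make_profiles(K, V, min_distance=separation * noise_sd * np.sqrt(V))
    P = np.full((K, K), (1.0 - stay_prob) / max(K - 1, 1))
    np.fill_diagonal(P, stay_prob)
    spec = RegimeSpec(profiles=profiles, transition_probs=P, noise_sd=noise_sd)
    return generate_regime_switching(spec, T=T, seed=seed)


@pytest.fixture
def small_series():
    """4 occasions x 2 variables, complete, occasion-indexed."""
    return LongitudinalSeries(
        subject_id="s1",
        timestamps=[0.0, 1.0, 2.0, 3.0],
        variables=["a", "b"],
        values=[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
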