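import pytest

from capsidkit import GeneratorTransition, simulate_thermogram

#: Generating parameters of the reference full-particle melting curve used
#: across tests: minor VP1-N-termini transition at 62.0 °C, major capsid
#: transition at 73.7 °C.
FP_FIRST = dict(dH=1.46e5, tm_c=62.0, amplitude=0.03)
FP_SECOND = dict(dH=3.21e5, tm_c=73.7, amplitude=0.25)


@pytest.fixture
def fp_thermogram():
    """Factory for full-particle-like two-transition thermograms."""
    def make(noise_sd=1e-3, seed=0):
        return simulate_thermogram(GeneratorTransition(**FP_FIRST),
                                   GeneratorTransition(**FP_SECOND),
                                   noise_sd=noise_sd, seed=seed)
    return make


@pytest.fixture
def ep_thermogram():
    """Factory for empty-particle-like single-transition thermograms
    (no VP1/VP2 first transition)."""
    def make(noise_sd=1e-3, seed=0):
        return simulate_thermogram(None,
                                   GeneratorTransition(2.78e5, 73.8, 0.25),
                                   noise_sd=noise_sd, seed=seed)
    return make
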