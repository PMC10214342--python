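import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rnherit as rh

settings.register_profile(
    "fast", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("fast")

# short-chain fits legitimately trip the Rhat warning; tests assert on
# diagnostics explicitly where convergence is the subject
warnings.filterwarnings("ignore", message="sampler convergence warning")
warnings.filterwarnings("ignore", category=FutureWarning)


def random_pedigree(rng: np.random.Generator, n: int,
                    p_founder: float = 0.4) -> rh.Pedigree:
    """Random acyclic pedigree: parents are drawn among earlier
    individuals, so offspring always follow their parents."""
    rows = []
    for i in range(n):
        ind = f"i{i}"
        if i < 2 or rng.random() < p_founder:
            rows.append({"individual": ind, "dam": None, "sire": None})
        else:
            dam, sire = rng.choice(i, size=2, replace=False)
            rows.append({"individual": ind, "dam": f"i{dam}",
                         "sire": f"i{sire}"})
    return rh.build_pedigree(rows)


@pytest.fixture(scope="session")
def tiny_sim() -> rh.SimulatedDataset:
    return rh.simulate_cortisol(rh.preset("tiny", seed=42))


@pytest.fixture(scope="session")
def tiny_prep(tiny_sim) -> rh.PreparedDataset:
    return rh.prepare(tiny_sim.samples, tiny_sim.events)


@pytest.fixture(scope="session")
def rn_fit(tiny_prep) -> rh.FitResult:
    spec = rh.build_model(tiny_prep, "reaction_norms")
    return rh.fit_model(
        spec, tiny_prep,
        rh.SamplerSettings(chains=2, iterations=800, warmup=300, seed=7))


@pytest.fixture(scope="session")
def animal_fit(tiny_sim, tiny_prep) -> rh.FitResult:
    spec = rh.build_model(tiny_prep, "full_heritability", A=tiny_sim.A)
    return rh.fit_model(
        spec, tiny_prep,
        rh.SamplerSettings(chains=2, iterations=800, warmup=300, seed=8))
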