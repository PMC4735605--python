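import numpy as np
import pytest
from hypothesis import settings

from foodwebopt.core import FoodWeb
from foodwebopt.generators import NicheParams, Scenario, generate_niche_web

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def chain():
    """A -> B -> C: the canonical three-level chain."""
    return FoodWeb(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def star():
    """One basal resource feeding two consumers."""
    return FoodWeb(["A", "B", "C"], [("A", "B"), ("A", "C")])


@pytest.fixture
def diamond():
    """A feeds B and C, both of which feed D (redundant energy paths)."""
    return FoodWeb(
        ["A", "B", "C", "D"], [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
    )


def equal_weight_scenario(web, e=0.2, cost=1.0, eta=1.0):
    """Scenario with identical risks, unit weights and costs everywhere."""
    if np.isscalar(e):
        e = {s: float(e) for s in web.species_ids}
    return Scenario(
        e=e,
        w={link: 1.0 for link in web.links},
        c={s: float(cost) for s in web.species_ids},
        U={s: 1.0 for s in web.species_ids},
        eta=eta,
    )


@pytest.fixture
def chain_scenario(chain):
    return equal_weight_scenario(chain)


def small_niche_webs(count, n=10, C=0.15, tolerance=0.3, seed0=0):
    """A reproducible batch of small niche-model webs for property tests."""
    return [
        generate_niche_web(NicheParams(n=n, C_target=C, tolerance=tolerance,
                                       seed=seed0 + i))
        for i in range(count)
    ]
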