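import numpy as np
import pytest
from hypothesis import settings

from ssrpopgen.simulate import IslandModelSpec, simulate_genotypes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_pop_strong():
    """Three clearly differentiated populations (island model F = 0.2)."""
    spec = IslandModelSpec(
        pop_sizes={"A": 50, "B": 50, "C": 50},
        n_loci=20,
        f_by_pop=0.2,
        missing_rate=0.0,
        seed=3,
    )
    g, truth = simulate_genotypes(spec)
    labels = np.array([{"A": 0, "B": 1, "C": 2}[p] for p in g.populations])
    return g, truth, labels


@pytest.fixture(scope="session")
def default_island():
    """The default four-population survey-like dataset."""
    return simulate_genotypes(IslandModelSpec(seed=11))
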