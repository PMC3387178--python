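import numpy as np
import pytest

from lineagesort import parse_newick
from lineagesort.synthetic import (
    ScenarioConfig,
    choose_cross_clade_hybrid,
    generate_scenario,
    simulate_birth_death_chronogram,
)

# compact study conditions for unit tests (full defaults are exercised
# by the acceptance suite)
SMALL = dict(n_species=8, crown_age=4.0)


@pytest.fixture(scope="session")
def chronogram8():
    """An 8-species birth-death chronogram (2 Ma crown)."""
    return simulate_birth_death_chronogram(8, seed=42)


@pytest.fixture(scope="session")
def null_scenario():
    """One fully generated no-hybrid study (8 species for speed)."""
    return generate_scenario(ScenarioConfig(seed=3, **SMALL))


@pytest.fixture(scope="session")
def hybrid_scenario():
    """Same study with one cross-clade cpDNA introgression injected."""
    base = generate_scenario(ScenarioConfig(seed=3, **SMALL))
    spec = choose_cross_clade_hybrid(base.species_chronogram)
    return generate_scenario(ScenarioConfig(seed=3, hybrid=spec, **SMALL))


def random_binary_tree(labels, rng, max_bl: float = 1.0):
    """Random topology by sequential attachment; random branch lengths."""
    newick = _random_newick(list(labels), rng, max_bl)
    return parse_newick(newick)


def _random_newick(labels, rng, max_bl):
    subtrees = [f"{lab}:{rng.uniform(0.01, max_bl):.4f}" for lab in labels]
    while len(subtrees) > 1:
        i, j = rng.choice(len(subtrees), size=2, replace=False)
        a, b = subtrees[int(i)], subtrees[int(j)]
        merged = f"({a},{b}):{rng.uniform(0.01, max_bl):.4f}"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (int(i), int(j))]
        subtrees.append(merged)
    return subtrees[0].rsplit(":", 1)[0] + ";"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
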