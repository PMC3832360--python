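import numpy as np
import pytest

from famgxe.pedigree import Individual, Pedigree, kinship2
from famgxe.simulate import SimulationConfig, simulate_study


def trio() -> Pedigree:
    return Pedigree([
        Individual("fa", "F1", None, None, "male"),
        Individual("mo", "F1", None, None, "female"),
        Individual("ch", "F1", "fa", "mo", "female"),
    ])


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return trio()


@pytest.fixture
def three_generations() -> Pedigree:
    """Two founder couples, their children married, two grandchildren,
    plus a half-sib via a second mating."""
    return Pedigree([
        Individual("gf1", "F1", None, None, "male"),
        Individual("gm1", "F1", None, None, "female"),
        Individual("gf2", "F1", None, None, "male"),
        Individual("gm2", "F1", None, None, "female"),
        Individual("pa", "F1", "gf1", "gm1", "male"),
        Individual("ma", "F1", "gf2", "gm2", "female"),
        Individual("c1", "F1", "pa", "ma", "male"),
        Individual("c2", "F1", "pa", "ma", "female"),
        Individual("ma2", "F1", None, None, "female"),
        Individual("h1", "F1", "pa", "ma2", "male"),
    ])


@pytest.fixture
def consanguineous() -> Pedigree:
    """Three generations with one full-sib mating (inbred grandchild)."""
    return Pedigree([
        Individual("f", "F1", None, None, "male"),
        Individual("m", "F1", None, None, "female"),
        Individual("s1", "F1", "f", "m", "male"),
        Individual("s2", "F1", "f", "m", "female"),
        Individual("k", "F1", "s1", "s2", "female"),
    ])


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic study under the default polygenic truth."""
    return simulate_study(SimulationConfig(seed=20240))


@pytest.fixture(scope="session")
def default_relationship(default_study):
    return kinship2(default_study.pedigree)


def sibpair_study(n_families: int, truth, seed: int, rng=None):
    """Two-parent two-child families with GxEE-model trait scores (no
    covariate effects); returns (scores Series, q array, relationship)."""
    from famgxe.simulate import simulate_pedigrees, simulate_tdee, simulate_traits

    cfg = SimulationConfig(
        n_families=n_families,
        role_counts=None,
        offspring_distribution=(0.0, 1.0, 0.0, 0.0),
        participation={"father": 1.0, "mother": 1.0},
        covariate_effects=None,
        seed=seed,
    )
    rng = rng or np.random.default_rng(seed)
    ped, phen = simulate_pedigrees(cfg, rng)
    rel = kinship2(ped)
    tdee, _ = simulate_tdee(ped, cfg, rng, ids=phen)
    df = simulate_traits(ped, tdee, truth, rng, rel=rel)
    scores = df.set_index("individual_id")[
        "trait" if "trait" in df.columns else df.columns[-1]
    ]
    q = (tdee.to_numpy() - tdee.mean()) / tdee.std(ddof=1)
    return scores, q, rel
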