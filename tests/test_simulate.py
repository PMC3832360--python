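import json

import numpy as np
import pandas as pd
import pytest

from famgxe.activity import EnergyCostTable, tdee_from_diary
from famgxe.gxee import GxEEParams
from famgxe.pedigree import kinship2, read_pedigree
from famgxe.simulate import (
    DEFAULT_TDEE_MOMENTS,
    SimulationConfig,
    _truncated_normal,
    gene_drop_kinship,
    polygenic_truth,
    scale_role_counts,
    simulate_pedigrees,
    simulate_study,
    simulate_tdee,
    simulate_traits,
)


def test_single_family_structure():
    cfg = SimulationConfig(
        n_families=1, role_counts=(1, 1, 1, 1), max_offspring=4, seed=0
    )
    ped, phen = simulate_pedigrees(cfg)
    assert len(ped) == 4
    assert len(phen) == 4
    kid = [i for i in ped.ids if not ped[i].is_founder]
    assert len(kid) == 2
    assert ped[kid[0]].father_id and ped[kid[0]].mother_id


def test_default_profile_counts_match_manifest(default_study):
    """Phenotyped totals equal the generator manifest: 958 subjects in 294
    families with the exact role profile."""
    truth = default_study.truth
    assert truth["n_phenotyped"] == 958
    assert truth["n_families"] == 294
    assert len(default_study.pedigree) == truth["n_individuals"]
    roles = default_study.phenotypes.groupby(
        [default_study.phenotypes["individual_id"].str.contains("_C"),
         default_study.phenotypes["sex"]]
    ).size()
    assert roles[(False, "male")] == 180
    assert roles[(False, "female")] == 253
    assert roles[(True, "male")] == 265
    assert roles[(True, "female")] == 260


def test_every_family_has_two_phenotyped_members(default_study):
    counts = default_study.phenotypes.groupby("family_id").size()
    assert counts.min() >= 2
    assert len(counts) == 294


def test_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(n_families=20, role_counts=scale_role_counts(20),
                           emit_diaries=True, seed=99)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for key in pa:
        assert open(pa[key], "rb").read() == open(pb[key], "rb").read()


def test_emitted_files_are_readable(tmp_path):
    cfg = SimulationConfig(n_families=15, role_counts=scale_role_counts(15), seed=5)
    study = simulate_study(cfg)
    paths = study.write(tmp_path)
    ped = read_pedigree(paths["pedigree"])
    assert len(ped) == len(study.pedigree)
    phen = pd.read_csv(paths["phenotypes"])
    assert set(phen["individual_id"]).issubset(set(ped.ids))
    truth = json.load(open(paths["truth"]))
    assert truth["n_phenotyped"] == len(phen)


def test_infeasible_role_counts_rejected():
    with pytest.raises(ValueError, match="cannot fit"):
        simulate_pedigrees(SimulationConfig(n_families=10, seed=0))


def test_tdee_truncation_and_moments():
    rng = np.random.default_rng(0)
    mean, sd = DEFAULT_TDEE_MOMENTS["father"]
    draws = _truncated_normal(rng, mean, sd, 500.0, size=10_000)
    assert draws.min() >= 500.0
    # truncation at 3.2 SD below the mean barely shifts the first moment
    assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(10_000) + 2.0


def test_role_conditional_tdee(default_study):
    phen = default_study.phenotypes
    fathers = phen[(~phen["individual_id"].str.contains("_C"))
                   & (phen["sex"] == "male")]
    sons = phen[(phen["individual_id"].str.contains("_C"))
                & (phen["sex"] == "male")]
    assert fathers["tdee"].mean() > sons["tdee"].mean()
    assert phen["tdee"].min() >= 500.0


def test_diary_roundtrip_recovers_drawn_tdee():
    cfg = SimulationConfig(n_families=10, role_counts=scale_role_counts(10),
                           emit_diaries=True, seed=13)
    study = simulate_study(cfg)
    costs = EnergyCostTable()
    weights = study.phenotypes.set_index("individual_id")["weight"]
    tdee = study.phenotypes.set_index("individual_id")["tdee"]
    assert len(study.diaries) == len(study.phenotypes)
    for rec in study.diaries:
        w = float(weights[rec.individual_id])
        back = tdee_from_diary(rec, w, costs).tdee
        quantum = w * costs.as_array()[-1] / 3.0  # one 15-min period's cost
        # tdee column is rounded to 2 decimals in the emitted table
        assert abs(back - float(tdee[rec.individual_id])) < quantum + 0.01


def test_gene_drop_parent_offspring_and_unrelated(trio_pedigree):
    rel, se = gene_drop_kinship(trio_pedigree, n_drops=100_000, seed=1)
    assert abs(rel.loc("fa", "ch") - 0.5) <= 3 * se[0, 2] + 1e-12
    assert rel.loc("fa", "mo") == 0.0  # unrelated founders share nothing
    assert rel.loc("fa", "fa") == 1.0


def test_gene_drop_matches_recursion_on_inbred_pedigree(consanguineous):
    rel_exact = kinship2(consanguineous)
    rel_mc, se = gene_drop_kinship(consanguineous, n_drops=50_000, seed=2)
    for a, i in enumerate(rel_exact.ids):
        for b, j in enumerate(rel_exact.ids):
            tol = 3 * max(se[a, b], 1e-12)
            assert abs(rel_mc.loc(i, j) - rel_exact.loc(i, j)) <= tol


def test_polygenic_truth_is_gxee_nesting():
    p = polygenic_truth(0.4, total_variance=2.0)
    assert p.gamma_g == 0.0 and p.lam == 0.0 and p.gamma_e == 0.0
    assert np.exp(p.alpha_g) == pytest.approx(0.8)
    assert np.exp(p.alpha_e) == pytest.approx(1.2)
    with pytest.raises(ValueError, match="h2"):
        polygenic_truth(1.2)


def test_sibpair_covariance_moment_check():
    """With equal TDEE inside each sib pair (rho_G = 1 exactly), the product
    y1*y2 has conditional mean 0.5*exp(alpha_g + gamma_g*q): the empirical
    mean over 20,000 pairs matches that expectation within 3 MC SEs."""
    truth = GxEEParams(alpha_g=-0.7, gamma_g=0.5, lam=0.3,
                       alpha_e=-0.7, gamma_e=0.0, mu=0.0)
    prods, expects = [], []
    batch, n_batches = 1000, 20  # 20,000 pairs total, bounded memory
    for b in range(n_batches):
        cfg = SimulationConfig(
            n_families=batch, role_counts=None,
            offspring_distribution=(0.0, 1.0, 0.0, 0.0),
            participation={"father": 0.0, "mother": 0.0},
            covariate_effects=None, seed=800 + b,
        )
        rng = np.random.default_rng(800 + b)
        ped, phen = simulate_pedigrees(cfg, rng)
        rel = kinship2(ped)
        qv = rng.normal(2500.0, 600.0, batch)
        tdee = pd.Series(np.repeat(qv, 2), index=phen)
        df = simulate_traits(ped, tdee, truth, rng, rel=rel)
        y = df["trait"].to_numpy().reshape(batch, 2)
        q_fam = ((tdee.to_numpy() - tdee.mean()) / tdee.std(ddof=1)).reshape(
            batch, 2)[:, 0]
        prods.append(y[:, 0] * y[:, 1])
        expects.append(0.5 * np.exp(truth.alpha_g + truth.gamma_g * q_fam))
    prod = np.concatenate(prods)
    expected = float(np.concatenate(expects).mean())
    se = prod.std(ddof=1) / np.sqrt(prod.size)
    assert abs(prod.mean() - expected) < 3 * se


def test_simulate_traits_gxee_requires_params():
    with pytest.raises(ValueError, match="gxee_params"):
        simulate_study(SimulationConfig(
            n_families=5, role_counts=scale_role_counts(5),
            trait_model="gxee", seed=0,
        ))
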