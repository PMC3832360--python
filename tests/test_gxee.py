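import numpy as np
import pytest

from conftest import sibpair_study
from famgxe.gxee import (
    GxEEParams,
    environmental_variance,
    evaluate_functions,
    fit_gxee,
    genetic_correlation,
    genetic_variance,
    gxee_covariance,
    gxee_loglik,
    GxEEFit,
)
from famgxe.pedigree import kinship2
from famgxe.polygenic import fit_polygenic, polygenic_loglik
from famgxe.simulate import polygenic_truth
from oracles import random_pedigree


def params(**kw):
    base = dict(alpha_g=-0.5, gamma_g=0.3, lam=0.2, alpha_e=-0.7, gamma_e=0.1, mu=0.0)
    base.update(kw)
    return GxEEParams(**base)


def test_variance_function_identities():
    p = params(alpha_g=np.log(2.0), gamma_g=0.0)
    assert genetic_variance(1.7, p) == pytest.approx(2.0)
    p = params(alpha_g=0.0, gamma_g=1.0)
    assert genetic_variance(np.log(3.0), p) == pytest.approx(3.0)
    with pytest.raises(OverflowError, match="rescale"):
        genetic_variance(3000.0, params(gamma_g=1.0))


def test_correlation_identities():
    assert genetic_correlation(0.4, 1.9, 0.0) == 1.0
    assert genetic_correlation(1.3, 1.3, 5.0) == 1.0
    assert genetic_correlation(np.log(2.0), 0.0, 1.0) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="lambda"):
        genetic_correlation(0.0, 1.0, -0.1)


def test_sibpair_offdiagonal_at_equal_exposure(trio_pedigree):
    """At equal q the correlation decay cancels: sib off-diagonal is
    (2*Phi) * sigma2_g(q) / ... = 0.5 * exp(alpha_g + gamma_g*q) for any lambda."""
    from famgxe.pedigree import Individual, Pedigree
    ped = Pedigree([
        Individual("fa", "F1", None, None, "male"),
        Individual("mo", "F1", None, None, "female"),
        Individual("s1", "F1", "fa", "mo", "male"),
        Individual("s2", "F1", "fa", "mo", "male"),
    ])
    rel = kinship2(ped)
    qv = 0.8
    for lam in (0.0, 0.5, 3.0):
        p = params(lam=lam)
        blocks = gxee_covariance(["s1", "s2"], [qv, qv], rel, p)
        expected = 0.5 * np.exp(p.alpha_g + p.gamma_g * qv)
        assert blocks["F1"][0, 1] == pytest.approx(expected, abs=1e-14)


def test_covariance_reduces_to_polygenic_under_null(three_generations):
    rel = kinship2(three_generations)
    ids = rel.ids
    q = np.linspace(-1, 1, len(ids))
    p = params(gamma_g=0.0, gamma_e=0.0, lam=0.0)
    blocks = gxee_covariance(ids, q, rel, p)
    omega = blocks["F1"]
    expected = np.exp(p.alpha_g) * rel.values + np.exp(p.alpha_e) * np.eye(len(ids))
    np.testing.assert_allclose(omega, expected, atol=1e-14)


@pytest.mark.parametrize("seed", range(5))
def test_covariance_elementwise_oracle(seed):
    """Vectorized block assembly equals the element-by-element definition
    on a random family, and the block is positive definite."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n_extra=3)
    rel = kinship2(ped)
    ids = rel.ids
    q = rng.normal(0, 1, len(ids))
    p = params(
        alpha_g=float(rng.normal(-0.5, 0.3)),
        gamma_g=float(rng.normal(0, 0.4)),
        lam=float(rng.uniform(0, 1)),
        alpha_e=float(rng.normal(-0.5, 0.3)),
        gamma_e=float(rng.normal(0, 0.4)),
    )
    omega = gxee_covariance(ids, q, rel, p)["FAM"]
    K = rel.values
    brute = np.empty_like(omega)
    for i in range(len(ids)):
        for j in range(len(ids)):
            sg_i = np.exp(0.5 * (p.alpha_g + p.gamma_g * q[i]))
            sg_j = np.exp(0.5 * (p.alpha_g + p.gamma_g * q[j]))
            rho = np.exp(-p.lam * abs(q[i] - q[j]))
            brute[i, j] = K[i, j] * rho * sg_i * sg_j
            if i == j:
                brute[i, j] += np.exp(p.alpha_e + p.gamma_e * q[i])
    np.testing.assert_allclose(omega, brute, atol=1e-12)
    assert np.linalg.eigvalsh(omega).min() > 0


def test_diagonal_is_total_variance(three_generations):
    rel = kinship2(three_generations)
    ids = rel.ids
    q = np.linspace(-2, 2, len(ids))
    p = params()
    omega = gxee_covariance(ids, q, rel, p)["F1"]
    inbred = np.diag(rel.values)  # all 1 here
    expected = inbred * genetic_variance(q, p) + environmental_variance(q, p)
    np.testing.assert_allclose(np.diag(omega), expected, atol=1e-14)


def test_loglik_reparameterization_invariance():
    truth = params()
    scores, q, rel = sibpair_study(50, truth, seed=4)
    c = 0.7
    shifted = GxEEParams(
        alpha_g=truth.alpha_g - truth.gamma_g * c,
        gamma_g=truth.gamma_g,
        lam=truth.lam,
        alpha_e=truth.alpha_e - truth.gamma_e * c,
        gamma_e=truth.gamma_e,
        mu=truth.mu,
    )
    ll = gxee_loglik(truth, scores, q, rel)
    ll_shift = gxee_loglik(shifted, scores, q + c, rel)
    assert ll_shift == pytest.approx(ll, abs=1e-9)


def test_constrained_fit_reproduces_polygenic():
    scores, q, rel = sibpair_study(100, polygenic_truth(0.4), seed=21)
    poly = fit_polygenic(scores, rel)
    con = fit_gxee(scores, q, rel,
                   constraints={"gamma_g", "gamma_e", "lam"}, anchor=poly)
    assert con.loglik == pytest.approx(poly.loglik, abs=1e-6)
    assert con.params.gamma_g == 0.0 and con.params.lam == 0.0
    full = fit_gxee(scores, q, rel, anchor=poly)
    assert full.loglik >= poly.loglik - 1e-6
    assert full.loglik >= con.loglik - 1e-6


def test_null_truth_yields_unbiased_near_zero_interaction():
    """Under a no-interaction truth the full-model slope estimates center on
    zero (within 3 Monte-Carlo SEs) and the decay rate stays near its
    boundary."""
    gammas, lams = [], []
    for seed in range(12):
        scores, q, rel = sibpair_study(300, polygenic_truth(0.4), seed=40 + seed)
        poly = fit_polygenic(scores, rel)
        fit = fit_gxee(scores, q, rel, anchor=poly)
        gammas.append(fit.params.gamma_g)
        lams.append(fit.params.lam)
    gammas = np.asarray(gammas)
    se = gammas.std(ddof=1) / np.sqrt(gammas.size)
    assert abs(gammas.mean()) < 3 * se
    assert np.median(lams) < 0.5


def test_fit_input_validation():
    scores, q, rel = sibpair_study(10, polygenic_truth(0.4), seed=3)
    with pytest.raises(ValueError, match="constrain"):
        fit_gxee(scores, q, rel, constraints={"alpha_g"})
    with pytest.raises(ValueError, match="constant exposure"):
        fit_gxee(scores, np.zeros_like(q), rel)
    with pytest.raises(ValueError, match="align"):
        fit_gxee(scores, q[:-1], rel)


def test_evaluate_functions_shapes_and_monotonicity():
    fit = GxEEFit(params=params(gamma_g=0.4, lam=0.6), loglik=0.0,
                  converged=True, constrained=frozenset())
    out = evaluate_functions(fit, np.linspace(-2, 2, 21), np.linspace(0, 3, 16))
    var = out["variance"]["sigma2_g"].to_numpy()
    assert np.all(np.diff(var) > 0)  # gamma_g > 0: increasing in q
    rho = out["correlation"]["rho_g"].to_numpy()
    assert rho[0] == pytest.approx(1.0)
    assert np.all(np.diff(rho) < 0)  # lambda > 0: decaying in dq
    surface = out["covariance_surface"]
    assert set(surface.columns) == {"q", "dq", "genetic_covariance"}


def test_evaluate_functions_flat_under_null_geometry():
    fit = GxEEFit(params=params(gamma_g=0.0, lam=0.0), loglik=0.0,
                  converged=True, constrained=frozenset())
    out = evaluate_functions(fit, np.linspace(-2, 2, 5), np.linspace(0, 2, 5))
    surf = out["covariance_surface"].pivot(index="q", columns="dq",
                                           values="genetic_covariance")
    arr = surf.to_numpy()
    np.testing.assert_allclose(arr - arr[:, [0]], 0.0, atol=1e-14)
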