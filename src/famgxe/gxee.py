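"""Continuous genotype-by-energy-expenditure (GxEE) interaction model.

Genetic and environmental variances are log-linear functions of an
environmental exposure q (standardized TDEE):

    sigma2_g(q) = exp(alpha_g + gamma_g * q)
    sigma2_e(q) = exp(alpha_e + gamma_e * q)

and the genetic correlation between two individuals decays exponentially in
their exposure difference:

    rho_G(q_i, q_j) = exp(-lambda * |q_i - q_j|)

The family covariance is assembled as

    Omega_ij = 2*Phi_ij * rho_G(q_i, q_j) * sigma_g(q_i) * sigma_g(q_j)
               + delta_ij * sigma2_e(q_i)

No interaction (gamma_g = 0, lambda = 0, gamma_e = 0) collapses this to the
polygenic model with sigma2_g = exp(alpha_g), sigma2_e = exp(alpha_e).
The exponential-decay kernel exp(-lambda*|dq|) is positive definite and the
Schur product with the PSD relationship block keeps every family covariance
positive definite for lambda >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from famgxe._blocks import BlockData, build_blocks, gaussian_loglik
from famgxe.polygenic import PolygenicFit, _scores_to_arrays

_MAX_EXPONENT = 700.0
_LAM_STARTS = (0.0, 0.1, 1.0)
_GAMMA_STARTS = (-0.5, 0.0, 0.5)

#: parameter order in the optimization vector
_PARAM_NAMES = ("mu", "alpha_g", "gamma_g", "lam", "alpha_e", "gamma_e")


@dataclass(frozen=True)
class GxEEParams:
    """Parameters of the GxEE covariance model (exposure on the q scale)."""

    alpha_g: float
    gamma_g: float
    lam: float
    alpha_e: float
    gamma_e: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.alpha_g, self.gamma_g, self.lam, self.alpha_e,
                self.gamma_e, self.mu)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("GxEE parameters must be finite")
        if self.lam < 0:
            raise ValueError("lambda (correlation decay rate) must be >= 0")

    def as_vector(self) -> np.ndarray:
        return np.array([self.mu, self.alpha_g, self.gamma_g, self.lam,
                         self.alpha_e, self.gamma_e])

    @classmethod
    def from_vector(cls, theta) -> "GxEEParams":
        mu, ag, gg, lam, ae, ge = (float(v) for v in theta)
        return cls(alpha_g=ag, gamma_g=gg, lam=lam, alpha_e=ae,
                   gamma_e=ge, mu=mu)


@dataclass
class GxEEFit:
    """Maximum-likelihood GxEE fit, possibly under parameter constraints."""

    params: GxEEParams
    loglik: float
    converged: bool
    constrained: frozenset[str]
    n: int = 0
    n_families: int = 0

    def params_on_kcal_scale(self, transform) -> dict:
        """Re-express parameters per kcal/day given the TDEE standardization.

        With q = (tdee - mean)/sd, gamma and lambda scale by 1/sd and the
        intercepts absorb -gamma*mean/sd.  Slopes/decay are also reported
        per 1000 kcal/day for readability.
        """
        sd, mean = transform.sd, transform.mean
        p = self.params
        return {
            "alpha_g": p.alpha_g - p.gamma_g * mean / sd,
            "gamma_g_per_kcal": p.gamma_g / sd,
            "gamma_g_per_1000kcal": 1000.0 * p.gamma_g / sd,
            "lam_per_kcal": p.lam / sd,
            "lam_per_1000kcal": 1000.0 * p.lam / sd,
            "alpha_e": p.alpha_e - p.gamma_e * mean / sd,
            "gamma_e_per_kcal": p.gamma_e / sd,
            "gamma_e_per_1000kcal": 1000.0 * p.gamma_e / sd,
        }


def genetic_variance(q, params: GxEEParams) -> np.ndarray | float:
    """sigma2_g(q) = exp(alpha_g + gamma_g*q); strictly positive."""
    return _exp_variance(q, params.alpha_g, params.gamma_g)


def environmental_variance(q, params: GxEEParams) -> np.ndarray | float:
    """sigma2_e(q) = exp(alpha_e + gamma_e*q); strictly positive."""
    return _exp_variance(q, params.alpha_e, params.gamma_e)


def _exp_variance(q, alpha, gamma):
    q = np.asarray(q, dtype=float)
    expo = alpha + gamma * q
    if np.any(np.abs(expo) > _MAX_EXPONENT):
        raise OverflowError(
            "log-variance exponent exceeds 700; rescale the exposure "
            "(standardize TDEE) before fitting"
        )
    out = np.exp(expo)
    return float(out) if out.ndim == 0 else out


def genetic_correlation(q_i, q_j, lam: float) -> np.ndarray | float:
    """rho_G = exp(-lambda*|q_i - q_j|), in (0, 1]; 1 iff lam = 0 or q_i = q_j."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out = np.exp(-lam * np.abs(np.asarray(q_i, dtype=float) - np.asarray(q_j, dtype=float)))
    return float(out) if out.ndim == 0 else out


def gxee_covariance(ids, q, rel, params: GxEEParams) -> dict[str, np.ndarray]:
    """Per-family GxEE covariance blocks, keyed by family id.

    ``ids`` and ``q`` are aligned; ``rel`` supplies the 2*Phi structure.
    Diagonals equal sigma2_g(q_i) + sigma2_e(q_i) for non-inbred members.
    """
    blocks = build_blocks(ids, np.zeros(len(ids)), rel, q=q)
    out: dict[str, np.ndarray] = {}
    for g in blocks.groups:
        omegas = _gxee_omega(params)(g)
        for fam, omega in zip(g.families, omegas):
            out[fam] = omega
    return out


def _gxee_omega(params: GxEEParams):
    """omega_fn over a SizeGroup; vectorized across families of equal size."""

    def omega_fn(group):
        expo_g = 0.5 * (params.alpha_g + params.gamma_g * group.q)
        expo_e = params.alpha_e + params.gamma_e * group.q
        if (np.max(np.abs(expo_g), initial=0.0) > 0.5 * _MAX_EXPONENT
                or np.max(np.abs(expo_e), initial=0.0) > _MAX_EXPONENT):
            return np.full_like(group.K, np.nan)
        sg = np.exp(expo_g)  # (n_fam, s) genetic SDs
        rho = np.exp(-params.lam * group.D)
        omega = group.K * rho * sg[:, :, None] * sg[:, None, :]
        idx = np.arange(group.size)
        omega[:, idx, idx] += np.exp(expo_e)
        return omega

    return omega_fn


def gxee_loglik(params: GxEEParams, scores, q, rel) -> float:
    """Gaussian log-likelihood of the GxEE model (sum over family blocks)."""
    ids, y = _scores_to_arrays(scores)
    blocks = build_blocks(ids, y, rel, q=q)
    return gaussian_loglik(blocks, params.mu, _gxee_omega(params))


_CONSTRAINABLE = {"gamma_g", "gamma_e", "lam"}


def fit_gxee(
    scores,
    q,
    rel,
    constraints=(),
    anchor: PolygenicFit | None = None,
) -> GxEEFit:
    """Maximum-likelihood GxEE fit under optional constraints.

    ``constraints`` names parameters frozen at zero, any subset of
    {gamma_g, gamma_e, lam}; freezing all three gives the polygenic model in
    exponential parameterization.  The fit is a multi-start bounded
    quasi-Newton search: a grid of starts over gamma_g and lambda (with
    moment-based intercepts), optionally anchored at a polygenic fit so the
    full model never falls below its nested polygenic optimum.
    """
    constraints = frozenset(constraints)
    unknown = constraints - _CONSTRAINABLE
    if unknown:
        raise ValueError(f"cannot constrain {sorted(unknown)}; "
                         f"allowed: {sorted(_CONSTRAINABLE)}")
    ids, y = _scores_to_arrays(scores)
    q = np.asarray(q, dtype=float)
    if q.shape != y.shape:
        raise ValueError("q must align with scores")
    if np.ptp(q) == 0:
        raise ValueError("constant exposure q: GxEE model unidentifiable")
    blocks = build_blocks(ids, y, rel, q=q)
    informative = sum(len(g.families) for g in blocks.groups if g.size >= 2)
    if informative < 2:
        raise ValueError("need at least 2 families with >= 2 phenotyped relatives")

    free = [
        k
        for k, name in enumerate(_PARAM_NAMES)
        if name in ("mu", "alpha_g", "alpha_e") or name not in constraints
    ]

    def nll(x_free, base):
        theta = base.copy()
        theta[free] = x_free
        ll = gaussian_loglik(
            blocks, theta[0], _gxee_omega(GxEEParams.from_vector(theta))
        )
        return 1e10 if not np.isfinite(ll) else -ll

    vtot = float(y.var(ddof=1))
    mu0 = float(y.mean())
    base = np.array([mu0, np.log(0.4 * vtot), 0.0, 0.0, np.log(0.6 * vtot), 0.0])

    starts = []
    gg_grid = _GAMMA_STARTS if "gamma_g" not in constraints else (0.0,)
    lam_grid = _LAM_STARTS if "lam" not in constraints else (0.0,)
    for gg in gg_grid:
        for lam in lam_grid:
            s = base.copy()
            s[2], s[3] = gg, lam
            starts.append(s)
    if anchor is not None:
        s = base.copy()
        s[1] = np.log(max(anchor.sigma2_g, 1e-8 * max(vtot, 1e-12)))
        s[4] = np.log(anchor.sigma2_e)
        s[0], s[2], s[3], s[5] = anchor.mu, 0.0, 0.0, 0.0
        starts.append(s)

    # cheap grid triage: refine only the most promising starts
    scored = sorted(starts, key=lambda s: nll(s[free], s))
    refine = scored[: min(3, len(scored))]
    if anchor is not None:
        anchored = starts[-1]
        if not any(anchored is s for s in refine):
            refine.append(anchored)

    bounds = [(0.0, None) if k == 3 else (None, None) for k in free]
    best = None
    any_ok = False
    for s in refine:
        res = optimize.minimize(
            lambda x: nll(x, s),
            s[free],
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 1000},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best[0]:
            theta = s.copy()
            theta[free] = res.x
            best = (res.fun, theta)
    if best is None or best[0] >= 1e10:
        raise RuntimeError(
            "GxEE fit failed to find a finite-likelihood optimum from any start"
        )
    fun, theta = best
    theta[3] = max(theta[3], 0.0)
    params = GxEEParams.from_vector(theta)
    return GxEEFit(
        params=params,
        loglik=float(-fun),
        converged=bool(any_ok),
        constrained=constraints,
        n=len(ids),
        n_families=blocks.n_families,
    )


def evaluate_functions(fit: GxEEFit, q_grid, dq_grid) -> dict[str, pd.DataFrame]:
    """Tabulate the fitted variance/correlation/covariance functions.

    Returns three frames: the genetic and environmental variance functions
    over ``q_grid``; the genetic correlation over ``dq_grid``; and the
    genetic covariance surface for a relative pair with 2*Phi = 1 at
    exposures (q, q + dq), cov = rho_G(dq) * sigma_g(q) * sigma_g(q + dq).
    """
    q_grid = np.asarray(q_grid, dtype=float)
    dq_grid = np.asarray(dq_grid, dtype=float)
    p = fit.params
    variance = pd.DataFrame({
        "q": q_grid,
        "sigma2_g": genetic_variance(q_grid, p),
        "sigma2_e": environmental_variance(q_grid, p),
    })
    correlation = pd.DataFrame({
        "dq": dq_grid,
        "rho_g": genetic_correlation(dq_grid, np.zeros_like(dq_grid), p.lam),
    })
    qq, dd = np.meshgrid(q_grid, dq_grid, indexing="ij")
    cov = (
        np.exp(-p.lam * np.abs(dd))
        * np.sqrt(genetic_variance(qq, p) * genetic_variance(qq + dd, p))
    )
    surface = pd.DataFrame({
        "q": qq.ravel(),
        "dq": dd.ravel(),
        "genetic_covariance": cov.ravel(),
    })
    return {"variance": variance, "correlation": correlation,
            "covariance_surface": surface}
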