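"""Polygenic variance-components model and heritability.

Trait scores within a family are modelled as multivariate normal with
covariance Omega = 2*Phi * sigma2_g + I * sigma2_e, where 2*Phi is the
expected additive relationship matrix.  Heritability is
h2 = sigma2_g / (sigma2_g + sigma2_e).  The likelihood factorizes over
families, and the null hypothesis h2 = 0 places sigma2_g on the boundary
of its parameter space, so the likelihood-ratio test uses the 50:50
mixture of a point mass at zero and a chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

from famgxe._blocks import BlockData, build_blocks, gaussian_loglik
from famgxe.lrt import LRTResult, lrt_statistic, mixture_sf, standard_contrasts

_H2_STARTS = (0.1, 0.4, 0.7)


@dataclass
class PolygenicFit:
    """Maximum-likelihood polygenic fit for one trait."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    mu: float
    n: int
    converged: bool
    n_families: int = 0

    @property
    def ci95(self) -> tuple[float, float]:
        """Wald 95% interval for h2, truncated to [0, 1]."""
        if not np.isfinite(self.se_h2):
            return (np.nan, np.nan)
        lo = max(0.0, self.h2 - 1.96 * self.se_h2)
        hi = min(1.0, self.h2 + 1.96 * self.se_h2)
        return (lo, hi)


def _scores_to_arrays(scores):
    """Accept an AdjustedTrait, a pandas Series (index = ids), or (ids, values)."""
    if hasattr(scores, "scores"):  # AdjustedTrait
        return list(scores.ids), scores.values()
    if isinstance(scores, pd.Series):
        return [str(i) for i in scores.index], scores.to_numpy(dtype=float)
    ids, values = scores
    return list(ids), np.asarray(values, dtype=float)


def _polygenic_omega(sigma2_g: float, sigma2_e: float):
    def omega_fn(group):
        eye = np.eye(group.size)
        return sigma2_g * group.K + sigma2_e * eye

    return omega_fn


def polygenic_loglik(params: dict, scores, rel) -> float:
    """Exact Gaussian log-likelihood of the polygenic model.

    ``params`` holds mu, sigma2_g (>= 0) and sigma2_e (> 0).  Evaluated as
    a sum of independent per-family block densities; singleton families
    contribute univariate normal terms.
    """
    mu = float(params["mu"])
    sg2 = float(params["sigma2_g"])
    se2 = float(params["sigma2_e"])
    if se2 <= 0:
        raise ValueError("sigma2_e must be positive")
    if sg2 < 0:
        raise ValueError("sigma2_g must be non-negative")
    ids, y = _scores_to_arrays(scores)
    blocks = build_blocks(ids, y, rel)
    return gaussian_loglik(blocks, mu, _polygenic_omega(sg2, se2))


def _loglik_from_blocks(blocks: BlockData, mu, sg2, se2) -> float:
    if se2 <= 0 or sg2 < 0:
        return -np.inf
    return gaussian_loglik(blocks, mu, _polygenic_omega(sg2, se2))


def fit_sporadic(scores, rel=None) -> PolygenicFit:
    """ML fit of the no-genetics (sigma2_g = 0) model: i.i.d. normal."""
    ids, y = _scores_to_arrays(scores)
    n = y.size
    mu = float(y.mean())
    s2 = float(np.mean((y - mu) ** 2))
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    return PolygenicFit(
        sigma2_g=0.0,
        sigma2_e=s2,
        h2=0.0,
        se_h2=np.nan,
        loglik=loglik,
        mu=mu,
        n=n,
        converged=True,
    )


def fit_polygenic(scores, rel, n_starts: int = 3) -> PolygenicFit:
    """Maximum-likelihood polygenic fit with boundary handling for sigma2_g.

    Optimizes (mu, log sigma2_e, sigma2_g) with sigma2_g box-constrained at
    zero so the h2 = 0 boundary is attainable, from multiple heritability
    starts; the best-likelihood solution is kept.  se(h2) comes from the
    inverse observed information via the delta method (NaN at the boundary,
    where the Wald approximation breaks down).
    """
    ids, y = _scores_to_arrays(scores)
    blocks = build_blocks(ids, y, rel)
    informative = sum(
        len(g.families) for g in blocks.groups if g.size >= 2
    )
    if informative < 2:
        raise ValueError(
            "need at least 2 families with >= 2 phenotyped relatives "
            f"(got {informative}); h2 is unidentifiable"
        )
    vtot = float(y.var(ddof=1))
    mu0 = float(y.mean())

    def nll(theta):
        mu, log_se2, sg2 = theta
        if log_se2 > 50 or log_se2 < -50:
            return 1e10
        ll = _loglik_from_blocks(blocks, mu, sg2, np.exp(log_se2))
        return 1e10 if not np.isfinite(ll) else -ll

    best = None
    any_ok = False
    for h2 in _H2_STARTS[:n_starts]:
        x0 = np.array([mu0, np.log((1 - h2) * vtot), h2 * vtot])
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(None, None), (None, None), (0.0, None)],
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError("polygenic fit failed from all starts")
    mu, log_se2, sg2 = best.x
    se2 = float(np.exp(log_se2))
    sg2 = float(max(sg2, 0.0))
    h2 = sg2 / (sg2 + se2)
    se_h2 = _se_h2(blocks, mu, sg2, se2)
    return PolygenicFit(
        sigma2_g=sg2,
        sigma2_e=se2,
        h2=float(h2),
        se_h2=se_h2,
        loglik=float(-best.fun),
        mu=float(mu),
        n=len(ids),
        converged=bool(any_ok),
        n_families=blocks.n_families,
    )


def _se_h2(blocks, mu, sg2, se2) -> float:
    """Delta-method SE of h2 from the observed information in natural parameters."""
    if sg2 <= 0:
        return float("nan")

    def nll_nat(theta):
        return -_loglik_from_blocks(blocks, theta[0], theta[1], theta[2])

    try:
        H = approx_hess(np.array([mu, sg2, se2]), nll_nat)
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float("nan")
    tot = sg2 + se2
    grad = np.array([0.0, se2 / tot**2, -sg2 / tot**2])
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


def h2_test(fit: PolygenicFit, scores, rel) -> LRTResult:
    """Boundary LRT of h2 > 0 against the sporadic (sigma2_g = 0) model.

    T = 2*(loglik_polygenic - loglik_sporadic), referred to the 50:50
    mixture of a point mass at zero and chi-square with 1 df; p = 1 at T = 0.
    """
    sporadic = fit_sporadic(scores)
    T = lrt_statistic(fit.loglik, sporadic.loglik)
    null = standard_contrasts()["h2_zero"]
    return LRTResult(
        contrast="h2_zero",
        T=T,
        null=null,
        p=mixture_sf(T, null),
        loglik_full=fit.loglik,
        loglik_reduced=sporadic.loglik,
    )
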